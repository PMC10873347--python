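"""Curve fitting for the biochemical assays.

Two models are estimated:

* actin-filament binding — the pyrene-quench titration is fit to a
  four-parameter variable-slope logistic in cofilin dose,
  ``S(C) = s0 + (sinf - s0) * C^h / (K^h + C^h)``,
  whose midpoint ``K`` is the half-maximal binding concentration K_0.5
  by construction (the slope ``h`` is a free nuisance parameter, not a
  mechanistic cooperativity estimate).  K_0.5 confidence intervals come
  from a seeded case-resampling bootstrap.

* LIMK kinase kinetics — per-substrate initial rates are extracted by
  least squares through the origin over the time course (product must stay
  within 10% of substrate), converted to absolute units via a gamma-32P
  standard curve when given, then fit to Michaelis-Menten
  ``v = kcat * [E] * [S] / (KM + [S])`` with Wald standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist


# ---------------------------------------------------------------------------
# Dose-response (actin binding)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillFit:
    """Sigmoidal dose-response estimates.

    ``k_half`` (K_0.5, uM) is the dose at half-maximal signal; ``hill`` the
    slope; ``s0``/``sinf`` the zero-dose and saturating plateaus (signal
    units).  ``k_half_ci`` is a bootstrap percentile interval when
    requested.
    """

    k_half: float
    hill: float
    s0: float
    sinf: float
    k_half_ci: tuple[float, float] | None
    residual_ss: float
    converged: bool
    n_points: int

    @property
    def top(self) -> float:
        return max(self.s0, self.sinf)

    @property
    def bottom(self) -> float:
        return min(self.s0, self.sinf)


def _logistic(conc, s0, sinf, log10_k, hill):
    k = 10.0**log10_k
    conc = np.asarray(conc, dtype=float)
    frac = np.zeros_like(conc)
    pos = conc > 0
    with np.errstate(over="ignore"):
        ratio = (conc[pos] / k) ** hill
    frac[pos] = ratio / (1.0 + ratio)
    return s0 + (sinf - s0) * frac


def _fit_logistic_once(conc, signal, p0=None):
    if p0 is None:
        s0_guess = float(signal[np.argmin(conc)])
        sinf_guess = float(signal[np.argmax(conc)])
        k_guess = half_max_crossing(conc, signal)
        if not np.isfinite(k_guess) or k_guess <= 0:
            pos = conc[conc > 0]
            k_guess = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
        p0 = [s0_guess, sinf_guess, np.log10(k_guess), 1.0]
    popt, pcov = curve_fit(
        _logistic,
        conc,
        signal,
        p0=p0,
        bounds=([-np.inf, -np.inf, -12.0, 0.01], [np.inf, np.inf, 12.0, 20.0]),
        maxfev=20000,
    )
    return popt, pcov


def half_max_crossing(conc: np.ndarray, signal: np.ndarray) -> float:
    """Dose at which the signal crosses halfway between its extremes,
    by linear interpolation between the bracketing measurements.

    Model-free oracle for K_0.5 on dense noiseless data.
    """
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    order = np.argsort(conc)
    c, s = conc[order], signal[order]
    half = (s[0] + s[-1]) / 2.0
    diff = s - half
    sign_change = np.nonzero(np.diff(np.signbit(diff)))[0]
    if len(sign_change) == 0:
        return np.nan
    i = sign_change[0]
    if diff[i] == 0:
        return float(c[i])
    t = diff[i] / (diff[i] - diff[i + 1])
    return float(c[i] + t * (c[i + 1] - c[i]))


def fit_dose_response(
    curve: pd.DataFrame,
    bootstrap_n: int = 1000,
    seed: int | None = None,
    conc_col: str = "concentration_uM",
    signal_col: str = "signal",
) -> HillFit:
    """Fit the four-parameter logistic to a binding titration.

    Requires at least 5 distinct concentrations.  K_0.5 and the slope are
    invariant to rescaling all signals (plateaus scale along).  With
    ``bootstrap_n`` > 0 a seeded case-resampling bootstrap yields a 95%
    percentile interval for K_0.5; non-convergence is reported via the
    ``converged`` flag rather than raised.
    """
    conc = curve[conc_col].to_numpy(float)
    signal = curve[signal_col].to_numpy(float)
    if len(np.unique(conc)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if np.allclose(signal, signal[0]):
        raise ValueError("signal is flat; dose-response is unidentifiable")

    try:
        popt, _ = _fit_logistic_once(conc, signal)
        converged = True
    except RuntimeError:
        popt = [np.nan] * 4
        converged = False
    s0, sinf, log10_k, hill = popt
    k_half = 10.0**log10_k if converged else np.nan
    rss = (
        float(np.sum((signal - _logistic(conc, *popt)) ** 2))
        if converged
        else np.nan
    )

    ci = None
    if converged and bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        estimates = []
        n = len(conc)
        for _ in range(bootstrap_n):
            take = rng.integers(0, n, size=n)
            if len(np.unique(conc[take])) < 5:
                continue
            try:
                # warm start at the full-data optimum
                b_opt, _ = _fit_logistic_once(conc[take], signal[take], p0=list(popt))
                estimates.append(10.0 ** b_opt[2])
            except RuntimeError:
                continue
        if len(estimates) >= max(20, bootstrap_n // 5):
            lo, hi = np.percentile(estimates, [2.5, 97.5])
            ci = (float(lo), float(hi))

    return HillFit(
        k_half=float(k_half),
        hill=float(hill),
        s0=float(s0),
        sinf=float(sinf),
        k_half_ci=ci,
        residual_ss=rss,
        converged=converged,
        n_points=len(conc),
    )


# ---------------------------------------------------------------------------
# Radiolabel standard curve
# ---------------------------------------------------------------------------


def calibrate_standard_curve(standards: pd.DataFrame) -> float:
    """Signal-per-nCi conversion: least-squares line through the origin.

    A single standard point still defines a proportionality (with a
    warning); identical zero-signal standards are rejected.
    """
    x = standards["nCi"].to_numpy(float)
    y = standards["signal"].to_numpy(float)
    if len(x) == 0 or np.all(x == 0) or np.all(y == 0):
        raise ValueError("standards carry no usable signal")
    if len(x) < 2:
        warnings.warn("single standard point: slope is unchecked proportionality")
    return float(np.sum(x * y) / np.sum(x * x))


# ---------------------------------------------------------------------------
# Michaelis-Menten kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten estimates: kcat (s^-1), KM (uM) with Wald SEs.

    95% confidence intervals use the t distribution with n - 2 residual
    degrees of freedom, the small-sample convention of nonlinear-regression
    software.
    """

    kcat: float
    km: float
    kcat_se: float
    km_se: float
    enzyme_nM: float
    rates: pd.DataFrame  # per-substrate initial rates (uM/s)

    @property
    def vmax_uM_per_s(self) -> float:
        return self.kcat * self.enzyme_nM * 1e-3

    def _t_crit(self) -> float:
        dof = len(self.rates) - 2
        if dof < 1:
            return np.nan
        return float(t_dist.ppf(0.975, dof))

    @property
    def kcat_ci(self) -> tuple[float, float]:
        h = self._t_crit() * self.kcat_se
        return (self.kcat - h, self.kcat + h)

    @property
    def km_ci(self) -> tuple[float, float]:
        h = self._t_crit() * self.km_se
        return (self.km - h, self.km + h)


def initial_rates(
    timecourse: pd.DataFrame,
    conversion: float | None = None,
    through_origin: bool = True,
) -> pd.DataFrame:
    """Per-substrate initial rate (uM/s) from the full time course.

    Ordinary least squares of product on time, through the origin by
    default (no product at t = 0).  ``conversion`` divides raw signal into
    product units (signal per uM equivalent, e.g. from the standard curve
    combined with specific activity).  Flags any substrate where product
    exceeds 10% of substrate, outside the initial-rate regime.
    """
    rows = []
    for s_conc, grp in timecourse.groupby("substrate_uM"):
        t = grp["time_min"].to_numpy(float) * 60.0
        col = "product_uM" if "product_uM" in grp else "signal"
        p = grp[col].to_numpy(float)
        if conversion is not None:
            p = p / conversion
        if through_origin:
            v = float(np.sum(t * p) / np.sum(t * t))
        else:
            v = float(np.polyfit(t, p, 1)[0])
        rows.append(
            {
                "substrate_uM": float(s_conc),
                "rate_uM_per_s": v,
                "initial_rate_ok": bool(np.all(p <= 0.1 * s_conc + 1e-12)),
            }
        )
    return pd.DataFrame(rows).sort_values("substrate_uM", ignore_index=True)


def _mm(s, kcat, km, e_uM):
    return kcat * e_uM * s / (km + s)


def fit_michaelis_menten(
    data: pd.DataFrame,
    enzyme_nM: float,
    conversion: float | None = None,
    weighting: str = "relative",
) -> MMFit:
    """Fit v = kcat*[E]*[S]/(KM+[S]) to a kinase dataset.

    ``data`` is either a time course (columns substrate_uM, time_min,
    product_uM or signal) from which initial rates are extracted, or a
    pre-computed rate table (columns substrate_uM, rate_uM_per_s).  Two
    substrate concentrations determine the parameters exactly (the
    Lineweaver-Burk closed form) but leave no residual degrees of freedom,
    so standard errors are NaN and a warning is raised below 3.

    ``weighting``: "relative" (default) weights residuals by 1/rate, the
    standard choice when measurement error is proportional to signal, as it
    is for densitometry of radiolabel incorporation; "uniform" for
    homoscedastic least squares.
    """
    if weighting not in ("relative", "uniform"):
        raise ValueError("weighting must be 'relative' or 'uniform'")
    if enzyme_nM <= 0:
        raise ValueError("enzyme concentration must be positive")
    if "rate_uM_per_s" in data.columns:
        rates = data[["substrate_uM", "rate_uM_per_s"]].copy()
    else:
        rates = initial_rates(data, conversion=conversion)
        if not rates["initial_rate_ok"].all():
            bad = rates.loc[~rates["initial_rate_ok"], "substrate_uM"].tolist()
            warnings.warn(f"product exceeds 10% of substrate at S = {bad} uM")
    s = rates["substrate_uM"].to_numpy(float)
    v = rates["rate_uM_per_s"].to_numpy(float)
    if len(s) < 2:
        raise ValueError("need at least 2 substrate concentrations")
    if len(s) < 3:
        warnings.warn("fewer than 3 substrate concentrations: SEs undefined")
    if np.any(v < 0):
        raise ValueError("negative fitted rate; data outside model range")

    e_uM = enzyme_nM * 1e-3
    kcat0 = max(v.max(), 1e-12) / e_uM
    km0 = float(np.median(s))
    # rates are tiny in absolute units; normalize residuals to O(1) so the
    # optimizer's ftol/gtol thresholds are meaningful
    v_scale = max(v.max(), 1e-300)
    sigma = None
    if weighting == "relative" and np.all(v > 0):
        sigma = v / v_scale
    popt, pcov = curve_fit(
        lambda ss, kcat, km: _mm(ss, kcat, km, e_uM) / v_scale,
        s,
        v / v_scale,
        p0=[kcat0, km0],
        sigma=sigma,
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
    )
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return MMFit(
        kcat=float(popt[0]),
        km=float(popt[1]),
        kcat_se=float(se[0]),
        km_se=float(se[1]),
        enzyme_nM=enzyme_nM,
        rates=rates,
    )


def normalize_rate_to_wt(
    rates: dict[str, float], reference: str = "WT"
) -> dict[str, float]:
    """Rates relative to a reference (the reference maps to exactly 1)."""
    if reference not in rates:
        raise ValueError(f"reference {reference!r} missing from rates")
    ref = rates[reference]
    if ref <= 0:
        raise ValueError("reference rate must be positive")
    return {k: v / ref for k, v in rates.items()}


def phospho_fraction(upper_band: float, lower_band: float) -> float:
    """Fraction phosphorylated from Phos-tag band intensities:
    upper / (upper + lower)."""
    if upper_band < 0 or lower_band < 0:
        raise ValueError("band intensities must be non-negative")
    total = upper_band + lower_band
    if total == 0:
        raise ValueError("both bands are zero")
    return upper_band / total
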