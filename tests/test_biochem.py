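"""Dose-response and Michaelis-Menten fitting against exact oracles."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import cofscan as cs


# ---- dose-response ---------------------------------------------------------


def test_noiseless_hill_parameters_recovered():
    spec = cs.BindingCurveSpec(k_half=1.0, hill=2.0, top=1.0, bottom=0.0)
    fit = cs.fit_dose_response(cs.simulate_binding_curve(spec), bootstrap_n=0)
    assert fit.converged
    assert fit.k_half == pytest.approx(1.0, rel=1e-6)
    assert fit.hill == pytest.approx(2.0, rel=1e-6)
    assert fit.top == pytest.approx(1.0, abs=1e-6)
    assert fit.bottom == pytest.approx(0.0, abs=1e-6)


def test_k_half_matches_half_max_interpolation_oracle():
    spec = cs.BindingCurveSpec(
        k_half=0.61, hill=1.5,
        concentrations=tuple(np.geomspace(0.001, 500, 2000)),
    )
    curve = cs.simulate_binding_curve(spec)
    crossing = cs.half_max_crossing(
        curve["concentration_uM"].to_numpy(), curve["signal"].to_numpy()
    )
    fit = cs.fit_dose_response(curve, bootstrap_n=0)
    assert fit.k_half == pytest.approx(crossing, rel=1e-3)
    assert fit.k_half == pytest.approx(0.61, rel=1e-6)


def test_scale_equivariance_of_binding_fit():
    spec = cs.BindingCurveSpec(k_half=0.61, noise_cv=0.05, seed=9)
    curve = cs.simulate_binding_curve(spec)
    scaled = curve.assign(signal=curve["signal"] * 37.0)
    a = cs.fit_dose_response(curve, bootstrap_n=0)
    b = cs.fit_dose_response(scaled, bootstrap_n=0)
    assert b.k_half == pytest.approx(a.k_half, rel=1e-6)
    assert b.hill == pytest.approx(a.hill, rel=1e-6)
    assert b.top == pytest.approx(37.0 * a.top, rel=1e-6)


def test_binding_fit_input_validation():
    flat = pd.DataFrame(
        {"concentration_uM": [0.1, 0.3, 1, 3, 10], "signal": [1.0] * 5}
    )
    with pytest.raises(ValueError, match="flat"):
        cs.fit_dose_response(flat, bootstrap_n=0)
    few = pd.DataFrame({"concentration_uM": [0.1, 1, 10], "signal": [1, 0.5, 0]})
    with pytest.raises(ValueError, match="at least 5"):
        cs.fit_dose_response(few, bootstrap_n=0)


def test_bootstrap_ci_brackets_estimate_and_is_seeded():
    spec = replace(cs.BINDING_PRESETS["WT"], noise_cv=0.05, seed=21)
    curve = cs.simulate_binding_curve(spec)
    a = cs.fit_dose_response(curve, bootstrap_n=100, seed=5)
    b = cs.fit_dose_response(curve, bootstrap_n=100, seed=5)
    assert a.k_half_ci == b.k_half_ci
    lo, hi = a.k_half_ci
    assert lo < a.k_half < hi


# ---- standard curve --------------------------------------------------------


def test_standard_curve_exact_slope():
    standards = pd.DataFrame({"nCi": [2.5, 5.0, 10.0], "signal": [25.0, 50.0, 100.0]})
    assert cs.calibrate_standard_curve(standards) == pytest.approx(10.0)


def test_standard_curve_single_point_warns():
    standards = pd.DataFrame({"nCi": [2.5], "signal": [25.0]})
    with pytest.warns(UserWarning, match="single standard"):
        slope = cs.calibrate_standard_curve(standards)
    assert slope == pytest.approx(10.0)


def test_standard_curve_rejects_dead_signal():
    standards = pd.DataFrame({"nCi": [2.5, 5.0], "signal": [0.0, 0.0]})
    with pytest.raises(ValueError):
        cs.calibrate_standard_curve(standards)


# ---- Michaelis-Menten ------------------------------------------------------


def test_noiseless_mm_recovers_generating_parameters():
    tc = cs.simulate_kinase_timecourse(cs.KINETIC_PRESETS["WT"])["timecourse"]
    fit = cs.fit_michaelis_menten(tc, enzyme_nM=2.0)
    assert fit.kcat == pytest.approx(0.20, rel=1e-6)
    assert fit.km == pytest.approx(9.0, rel=1e-6)


def test_half_saturation_identity():
    tc = cs.simulate_kinase_timecourse(cs.KINETIC_PRESETS["G4F"])["timecourse"]
    fit = cs.fit_michaelis_menten(tc, enzyme_nM=2.0)
    v_at_km = fit.kcat * fit.enzyme_nM * 1e-3 * fit.km / (fit.km + fit.km)
    assert v_at_km == pytest.approx(fit.vmax_uM_per_s / 2, rel=1e-9)


def test_two_point_fit_equals_lineweaver_burk_closed_form():
    e_uM = 0.002
    kcat, km = 0.3, 7.0
    s = np.array([2.0, 20.0])
    v = kcat * e_uM * s / (km + s)
    rates = pd.DataFrame({"substrate_uM": s, "rate_uM_per_s": v})
    # closed form from the double-reciprocal line through the two points
    inv_s, inv_v = 1 / s, 1 / v
    slope = (inv_v[1] - inv_v[0]) / (inv_s[1] - inv_s[0])
    intercept = inv_v[0] - slope * inv_s[0]
    vmax_lb, km_lb = 1 / intercept, slope / intercept
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cs.fit_michaelis_menten(rates, enzyme_nM=2.0)
    assert fit.kcat == pytest.approx(vmax_lb / e_uM, rel=1e-6)
    assert fit.km == pytest.approx(km_lb, rel=1e-6)


def test_mm_input_validation():
    rates = pd.DataFrame({"substrate_uM": [1.0], "rate_uM_per_s": [1e-4]})
    with pytest.raises(ValueError, match="at least 2"):
        cs.fit_michaelis_menten(rates, enzyme_nM=2.0)
    neg = pd.DataFrame(
        {"substrate_uM": [1.0, 5.0, 10.0], "rate_uM_per_s": [-1e-4, 1e-4, 2e-4]}
    )
    with pytest.raises(ValueError, match="negative"):
        cs.fit_michaelis_menten(neg, enzyme_nM=2.0)
    with pytest.raises(ValueError, match="enzyme"):
        cs.fit_michaelis_menten(neg, enzyme_nM=0.0)


def test_initial_rates_flag_regime_violations():
    tc = pd.DataFrame(
        {
            "substrate_uM": [1.0, 1.0, 10.0, 10.0],
            "time_min": [5.0, 10.0, 5.0, 10.0],
            "product_uM": [0.2, 0.4, 0.01, 0.02],  # first exceeds 10% of 1 uM
        }
    )
    rates = cs.initial_rates(tc)
    assert not rates.loc[rates.substrate_uM == 1.0, "initial_rate_ok"].iloc[0]
    assert rates.loc[rates.substrate_uM == 10.0, "initial_rate_ok"].iloc[0]
    # OLS through the origin on an exact line recovers the slope
    assert rates.loc[rates.substrate_uM == 10.0, "rate_uM_per_s"].iloc[0] == (
        pytest.approx(0.02 / 600.0)
    )


def test_standard_curve_conversion_applies_to_rates():
    spec = replace(cs.KINETIC_PRESETS["WT"], signal_per_nCi=7.0)
    out = cs.simulate_kinase_timecourse(spec)
    conv = cs.calibrate_standard_curve(out["standards"])
    assert conv == pytest.approx(7.0)


# ---- normalization and band ratios ----------------------------------------


def test_rates_normalized_to_wild_type():
    rel = cs.normalize_rate_to_wt({"WT": 2.0, "mut": 0.8})
    assert rel["WT"] == 1.0
    assert rel["mut"] == pytest.approx(0.4)
    with pytest.raises(ValueError, match="reference"):
        cs.normalize_rate_to_wt({"mut": 1.0})
    with pytest.raises(ValueError):
        cs.normalize_rate_to_wt({"WT": 0.0, "mut": 1.0})


def test_slow_substrate_rate_ratio_recovered():
    """A substrate with 40% of the reference kcat and equal KM yields a
    normalized rate of 0.4 from matched simulated assays."""
    ref = cs.KinaseAssaySpec(kcat=0.20, km=9.0, substrate_uM=(2.0,))
    slow = cs.KinaseAssaySpec(kcat=0.08, km=9.0, substrate_uM=(2.0,))
    rates = {}
    for name, spec in [("cofilin", ref), ("twinfilin", slow)]:
        tc = cs.simulate_kinase_timecourse(spec, with_standards=False)["timecourse"]
        rates[name] = cs.initial_rates(tc)["rate_uM_per_s"].iloc[0]
    rel = cs.normalize_rate_to_wt(rates, reference="cofilin")
    assert rel["twinfilin"] == pytest.approx(0.4, rel=1e-9)


@pytest.mark.parametrize(
    "upper, lower, expected",
    [(0.0, 50.0, 0.0), (50.0, 50.0, 0.5), (30.0, 70.0, 0.3)],
)
def test_phospho_fraction(upper, lower, expected):
    assert cs.phospho_fraction(upper, lower) == pytest.approx(expected)


def test_phospho_fraction_rejects_empty_lanes():
    with pytest.raises(ValueError):
        cs.phospho_fraction(0.0, 0.0)
    with pytest.raises(ValueError):
        cs.phospho_fraction(-1.0, 2.0)
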