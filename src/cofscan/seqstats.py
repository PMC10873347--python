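"""Positional sequence statistics over scored variant sets.

Three views of how residues shape the screen outcome:

* per-(position, residue) mean scores and score distributions, averaging
  over exactly the library sequences carrying that residue (800 sequences
  per residue at positions 2/4/5; 8000 at the Ser/Thr position 3);
* probability logos: letter heights are signed -log10 exact binomial tail
  probabilities of the foreground residue count against the library
  background composition, with a Bonferroni-corrected significance line;
* pairwise residue covariation: observed joint counts in a selected set
  against the independence expectation from the set's own positional
  marginals, with exact binomial tests.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .library import AA_ALPHABET, PHOSPHOACCEPTORS, POSITIONS

#: Exact residue composition of the full 16,000-member design.
DESIGN_BACKGROUND = {
    2: {aa: 1 / 20 for aa in AA_ALPHABET},
    3: {"S": 0.5, "T": 0.5},
    4: {aa: 1 / 20 for aa in AA_ALPHABET},
    5: {aa: 1 / 20 for aa in AA_ALPHABET},
}

#: Residue-position cells tested by default in a logo (20 + 2 + 20 + 20).
N_LOGO_CELLS = sum(len(v) for v in DESIGN_BACKGROUND.values())

_TINY = np.nextafter(0.0, 1.0)  # smallest positive subnormal double


def _position_residues(position: int) -> str:
    if position not in POSITIONS:
        raise ValueError(f"position must be one of {POSITIONS}")
    return PHOSPHOACCEPTORS if position == 3 else AA_ALPHABET


def _residue_at(index: pd.Index, position: int) -> pd.Series:
    return index.str[position - 2]


# ---------------------------------------------------------------------------
# Heat maps and distribution summaries
# ---------------------------------------------------------------------------


def residue_position_means(
    scores: pd.DataFrame, contrast: str = "function_mean"
) -> pd.DataFrame:
    """Mean score per (position, residue) cell.

    Each cell averages the score over every library sequence containing the
    residue at that position: 800 sequences at positions 2, 4 and 5, 8000
    at position 3, when the score table covers the complete design space.
    """
    values = scores[contrast]
    rows = []
    for pos in POSITIONS:
        residue = _residue_at(scores.index, pos)
        grouped = values.groupby(residue.to_numpy())
        means, counts = grouped.mean(), grouped.count()
        for aa in _position_residues(pos):
            rows.append(
                {
                    "position": pos,
                    "residue": aa,
                    "mean_score": means.get(aa, np.nan),
                    "n": int(counts.get(aa, 0)),
                }
            )
    return pd.DataFrame(rows)


def score_distribution_summary(
    scores: pd.DataFrame, position: int, contrast: str = "function_mean"
) -> pd.DataFrame:
    """Box statistics of the score per residue at one position.

    Median, quartiles and 10th/90th percentiles (linear interpolation
    between order statistics) over the sequences carrying each residue.
    """
    values = scores[contrast]
    residue = _residue_at(scores.index, position)
    rows = []
    for aa in _position_residues(position):
        v = values[residue.to_numpy() == aa].dropna().to_numpy()
        if len(v) == 0:
            rows.append({"position": position, "residue": aa, "n": 0})
            continue
        p10, q25, med, q75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
        rows.append(
            {
                "position": position,
                "residue": aa,
                "median": med,
                "q25": q25,
                "q75": q75,
                "p10": p10,
                "p90": p90,
                "n": len(v),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Binomial probability logos
# ---------------------------------------------------------------------------


def binomial_logo(
    foreground: list[str] | tuple[str, ...],
    background: dict[int, dict[str, float]] | None = None,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Signed -log10 exact binomial tail heights per residue-position.

    For residue ``a`` at position ``i`` seen ``k`` times among ``n``
    foreground sequences against background probability ``p``:
    overrepresented cells (k >= n*p) get height -log10 P(X >= k), computed
    by the exact upper tail; underrepresented cells get -(-log10 P(X <= k))
    from the exact lower tail.  The significance line is
    -log10(alpha / m) with Bonferroni divisor ``m`` (default: the 62 tested
    cells).  Tail probabilities are floored at the smallest positive double
    so heights stay finite.
    """
    n = len(foreground)
    if n == 0:
        raise ValueError("empty foreground set")
    background = DESIGN_BACKGROUND if background is None else background
    fg = pd.Index(foreground)
    m = bonferroni_m if bonferroni_m is not None else sum(
        len(v) for v in background.values()
    )
    threshold = -np.log10(alpha / m)
    rows = []
    for pos in POSITIONS:
        residue_counts = _residue_at(fg, pos).value_counts()
        for aa, p_bg in background[pos].items():
            k = int(residue_counts.get(aa, 0))
            if k >= n * p_bg:
                tail = binom.sf(k - 1, n, p_bg)  # P(X >= k)
                height = -np.log10(max(tail, _TINY))
            else:
                tail = binom.cdf(k, n, p_bg)  # P(X <= k)
                height = np.log10(max(tail, _TINY))
            rows.append(
                {
                    "position": pos,
                    "residue": aa,
                    "k": k,
                    "n": n,
                    "p_bg": p_bg,
                    "height": height,
                    "threshold": threshold,
                    "significant": abs(height) >= threshold,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairwise residue covariation
# ---------------------------------------------------------------------------


def _two_sided_binom_p(k: np.ndarray, n: int, p: np.ndarray) -> np.ndarray:
    """Two-sided exact binomial p by tail doubling, capped at 1."""
    lower = binom.cdf(k, n, p)
    upper = binom.sf(k - 1, n, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def pairwise_covariation(
    selected: list[str] | tuple[str, ...],
    positions: tuple[int, int] | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    expected_floor: float = 1e-9,
    background: dict[int, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Residue-pair linkage within a selected set against independence.

    For each residue pair (a at position i, b at position j) the expected
    joint count under positional independence is N * p_i(a) * p_j(b); by
    default the marginals come from the selected set itself, so the test
    asks whether the two positions covary within the set (pass
    ``background`` to test against the library composition instead).
    Each cell gets an exact two-sided binomial p-value (n = N,
    p = p_i(a) * p_j(b)); Bonferroni correction runs over all tested cells
    of the requested position pair(s).  Expected counts over each pair's
    full residue grid sum to N.
    """
    if len(selected) == 0:
        raise ValueError("empty selected set")
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    n = len(selected)
    idx = pd.Index(selected)
    pairs = (
        [tuple(sorted(positions))]
        if positions is not None
        else list(combinations(POSITIONS, 2))
    )
    for i, j in pairs:
        if i not in POSITIONS or j not in POSITIONS or i == j:
            raise ValueError(f"invalid position pair ({i}, {j})")

    def marginal(pos: int) -> pd.Series:
        if background is not None:
            return pd.Series(background[pos], dtype=float)
        counts = _residue_at(idx, pos).value_counts()
        return counts.reindex(list(_position_residues(pos)), fill_value=0) / n

    frames = []
    for i, j in pairs:
        p_i, p_j = marginal(i), marginal(j)
        res_i = _residue_at(idx, i).to_numpy()
        res_j = _residue_at(idx, j).to_numpy()
        joint = (
            pd.crosstab(res_i, res_j)
            .reindex(index=p_i.index, columns=p_j.index, fill_value=0)
            .to_numpy()
        )
        p_null = np.outer(p_i.to_numpy(), p_j.to_numpy())
        expected = n * p_null
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_ratio = np.log2(joint / expected)
        defined = (expected >= expected_floor) & (joint > 0)
        log2_ratio = np.where(defined, log2_ratio, np.nan)
        pvals = np.where(
            p_null > 0, _two_sided_binom_p(joint, n, np.clip(p_null, _TINY, 1)), 1.0
        )
        ai, bj = np.meshgrid(
            np.arange(len(p_i)), np.arange(len(p_j)), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "pos_i": i,
                    "pos_j": j,
                    "res_i": p_i.index.to_numpy()[ai.ravel()],
                    "res_j": p_j.index.to_numpy()[bj.ravel()],
                    "observed": joint.ravel(),
                    "expected": expected.ravel(),
                    "log2_obs_exp": log2_ratio.ravel(),
                    "p_value": pvals.ravel(),
                    "tested": p_null.ravel() > 0,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    m = int(out["tested"].sum()) if correction == "bonferroni" else 1
    out["p_adjusted"] = np.minimum(1.0, out["p_value"] * m)
    out["significant"] = out["tested"] & (out["p_adjusted"] < alpha)
    return out


def write_stats_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
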