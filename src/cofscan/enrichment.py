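"""Enrichment scoring: relative representation, log2 fold changes, ranks.

A variant's relative representation in a sample is its read count divided
by the sample's total valid read count (optionally with a pseudocount to
keep log-ratios finite).  Scores are per-replicate log2 ratios of relative
representation between two timepoints:

* ``function``   — glucose T0 -> T2 (kinase repressed; growth rescue)
* ``limk_glu``   — glucose T1 -> T3 (kinase repressed arm of the LIMK axis)
* ``limk_gal``   — galactose T1 -> T3 (LIMK1 induced)

Variants are ranked by the mean of the per-replicate log2 fold changes on
the function contrast (rank 1 = most enriched, ties broken lexicographically
by variant string); the enriched set is mean > 0, strictly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import CountMatrix
from .design import ScreenDesign


@dataclass(frozen=True)
class ContrastSpec:
    label: str
    start: str
    end: str
    condition: str

    def __post_init__(self):
        order = ("T0", "T1", "T2", "T3")
        if self.start in order and self.end in order:
            if order.index(self.start) >= order.index(self.end):
                raise ValueError("contrast start must precede end")


#: The screen's three contrasts.
CONTRASTS = (
    ContrastSpec("function", "T0", "T2", "glucose"),
    ContrastSpec("limk_glu", "T1", "T3", "glucose"),
    ContrastSpec("limk_gal", "T1", "T3", "galactose"),
)

DEFAULT_PSEUDOCOUNT = 0.5


def sample_frequencies(
    counts: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Relative representation per sample: (count + pc) / sum(count + pc)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    padded = counts.astype(float) + pseudocount
    totals = padded.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample(s) with pseudocount 0: {bad}")
    return padded / totals


def log2_enrichment(freq_end: pd.Series, freq_start: pd.Series) -> pd.Series:
    """Per-variant log2(freq_end / freq_start); NaN where either is zero.

    Antisymmetric under swapping start and end.  Zero frequencies (possible
    only at pseudocount 0) are flagged as NaN rather than +/-inf so they can
    be excluded from replicate means and ranking.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(freq_end.to_numpy(float) / freq_start.to_numpy(float))
    lfc[~np.isfinite(lfc)] = np.nan
    return pd.Series(lfc, index=freq_end.index)


def replicate_mean_and_rank(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean over valid replicates, descending rank, enriched flag.

    ``per_replicate`` has one column per replicate of log2 fold changes.
    The mean is the unweighted average over non-NaN replicates; variants
    invalid in all replicates are left unranked (rank NaN).  Ties rank
    deterministically in lexicographic variant order.
    """
    mean = per_replicate.mean(axis=1, skipna=True)
    n_valid = per_replicate.notna().sum(axis=1)
    out = pd.DataFrame({"mean": mean, "n_valid_reps": n_valid})
    # stable sort on a lexicographically pre-sorted index breaks ties by variant
    ranked = out[out["n_valid_reps"] > 0]
    ranked = ranked.loc[ranked.index.sort_values()].sort_values(
        "mean", ascending=False, kind="stable"
    )
    out["rank"] = pd.Series(
        np.arange(1, len(ranked) + 1, dtype=float), index=ranked.index
    )
    out["enriched"] = out["mean"] > 0
    return out


def score_screen(
    counts: CountMatrix | pd.DataFrame,
    design: ScreenDesign | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    contrasts: tuple[ContrastSpec, ...] = CONTRASTS,
) -> pd.DataFrame:
    """Full scoring table for a screen.

    Returns one row per variant with per-replicate and mean log2 fold
    changes for every contrast (columns ``{label}_rep{r}`` and
    ``{label}_mean``), the function-contrast ``rank`` and ``enriched`` flag,
    and the number of valid replicates per contrast.
    """
    design = design or ScreenDesign()
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    freqs = sample_frequencies(table, pseudocount)
    out = pd.DataFrame(index=table.index)
    for spec in contrasts:
        reps = {}
        for r in range(1, design.n_replicates + 1):
            start = freqs[design.sample_id(r, spec.condition, spec.start)]
            end = freqs[design.sample_id(r, spec.condition, spec.end)]
            reps[f"{spec.label}_rep{r}"] = log2_enrichment(end, start)
        rep_df = pd.DataFrame(reps)
        out = out.join(rep_df)
        out[f"{spec.label}_mean"] = rep_df.mean(axis=1, skipna=True)
        out[f"{spec.label}_n_valid"] = rep_df.notna().sum(axis=1)
    summary = replicate_mean_and_rank(
        out[[f"function_rep{r}" for r in range(1, design.n_replicates + 1)]]
    )
    out["rank"] = summary["rank"]
    out["enriched"] = summary["enriched"]
    return out


def select_enriched(scores: pd.DataFrame, threshold: float = 0.0) -> list[str]:
    """Variants whose mean function log2 fold change strictly exceeds
    ``threshold`` (default 0)."""
    mask = scores["function_mean"] > threshold
    return list(scores.index[mask.fillna(False)])


def top_ranked(scores: pd.DataFrame, n: int) -> list[str]:
    """The ``n`` most enriched variants by mean function rank."""
    ranked = scores["rank"].dropna().sort_values()
    return list(ranked.index[:n])


def write_enrichment_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="variant")


def read_enrichment_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant")
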