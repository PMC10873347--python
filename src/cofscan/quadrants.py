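"""LIMK-sensitivity quadrant classification of functional variants.

The dual-condition screen places every variant in a plane: mean log2 fold
change T1->T3 in glucose (kinase repressed) on one axis, the same contrast
in galactose (LIMK1 induced) on the other.  Functional variants (enriched
on the glucose axis) split into LIMK-sensitive (depleted under the kinase)
and LIMK-resistant (still enriched, or unchanged, under the kinase).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

CALLS = (
    "functional_sensitive",
    "functional_resistant",
    "nonfunctional_depleted",
    "nonfunctional_other",
)


def classify_quadrants(
    scores: pd.DataFrame,
    glucose_col: str = "limk_glu_mean",
    galactose_col: str = "limk_gal_mean",
    margin: float = 0.0,
) -> pd.DataFrame:
    """Quadrant call per variant from the two LIMK-axis means.

    functional = glucose-axis mean > margin; sensitive = functional AND
    galactose-axis mean < -margin; a galactose-axis tie (exactly 0 at the
    default margin) counts as resistant, so "sensitive" always means strict
    depletion.  Variants missing either axis are reported ``unclassified``.
    Returns a DataFrame with the two scores and the ``call`` column.
    """
    glu = scores[glucose_col]
    gal = scores[galactose_col]
    call = np.select(
        [
            glu.isna() | gal.isna(),
            (glu > margin) & (gal < -margin),
            (glu > margin),
            (glu <= margin) & (gal < -margin),
        ],
        ["unclassified", "functional_sensitive", "functional_resistant",
         "nonfunctional_depleted"],
        default="nonfunctional_other",
    )
    return pd.DataFrame(
        {"glucose_score": glu, "galactose_score": gal, "call": call},
        index=scores.index,
    )


def sensitivity_summary(
    calls: pd.DataFrame, stratify_by: int | None = None
) -> pd.DataFrame:
    """Fraction of functional variants that are LIMK-sensitive.

    With ``stratify_by`` a library position (2-5), counts and fractions are
    reported per residue at that position (e.g. position 3 splits the
    summary by Ser vs Thr phosphoacceptor); otherwise a single overall row.
    """
    functional = calls[calls["call"].isin(
        ["functional_sensitive", "functional_resistant"])]
    if functional.empty:
        raise ValueError("no functional variants to summarize")
    if stratify_by is None:
        groups = {"all": functional}
    else:
        if stratify_by not in (2, 3, 4, 5):
            raise ValueError("stratify_by must be a library position (2-5)")
        idx = stratify_by - 2
        groups = {
            res: sub for res, sub in functional.groupby(
                functional.index.str[idx])
        }
    rows = []
    for name, sub in groups.items():
        n_sens = int((sub["call"] == "functional_sensitive").sum())
        rows.append(
            {
                "group": name,
                "n_functional": len(sub),
                "n_sensitive": n_sens,
                "fraction_sensitive": n_sens / len(sub),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def write_quadrants_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index_label="variant")
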