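"""Amplicon read counting: FASTQ -> validated count matrix over the design.

Each read is framed by exact-match 5'/3' anchors around a 12-nt variable
region, translated codon-by-codon with the standard genetic code, and
checked against the library design (position-3 codon must be ACC or AGC).
Rejections are data, not errors: every read lands in exactly one QC
category and the categories partition the read total per sample.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .library import (
    DEFAULT_ANCHORS,
    POSITION3_CODONS,
    enumerate_library,
    translate_codon,
)

#: Mutually exclusive read outcomes.
QC_CATEGORIES = ("valid", "anchor_fail", "frame_fail", "codon_fail", "off_design")

INSERT_LENGTH = 12


@dataclass(frozen=True)
class ReadDecodeResult:
    outcome: str  # one of QC_CATEGORIES (valid reads report "valid")
    variant: str | None = None


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts per variant per sample, plus per-sample QC.

    The variant index always covers the full 16,000-member design space,
    zero-count variants included, so downstream frequency denominators are
    well defined.  ``qc`` rows are samples, columns the QC categories; the
    categories sum to the sample's total read count.
    """

    counts: pd.DataFrame
    qc: pd.DataFrame

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        """Valid on-design reads per sample (the frequency denominator)."""
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path, qc_path: str | Path | None = None) -> None:
        self.counts.to_csv(path, sep="\t")
        if qc_path is not None:
            self.qc.to_csv(qc_path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, qc_path: str | Path | None = None):
        counts = pd.read_csv(path, sep="\t", index_col="variant")
        counts = counts.reindex(enumerate_library()).fillna(0).astype(np.int64)
        if qc_path is not None:
            qc = pd.read_csv(qc_path, sep="\t", index_col=0)
        else:
            qc = pd.DataFrame(
                0, index=counts.columns, columns=list(QC_CATEGORIES)
            ).assign(valid=counts.sum(axis=0))
        return cls(counts=counts, qc=qc)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CountMatrix":
        """Wrap a variant x sample count table (e.g. simulator output)."""
        counts = counts.reindex(enumerate_library()).fillna(0).astype(np.int64)
        counts.index.name = "variant"
        qc = pd.DataFrame(0, index=counts.columns, columns=list(QC_CATEGORIES))
        qc["valid"] = counts.sum(axis=0)
        return cls(counts=counts, qc=qc)


def extract_variable_region(
    read: str, anchors: tuple[str, str] = DEFAULT_ANCHORS
) -> tuple[str, str | None]:
    """Exact-match anchor framing of the 12-nt insert.

    Returns ("ok", insert) when both anchors are found with exactly 12 nt
    between them, ("anchor_fail", None) when either anchor is absent, and
    ("frame_fail", None) when the gap is not 12 nt.
    """
    a5, a3 = anchors
    i5 = read.find(a5)
    if i5 < 0:
        return "anchor_fail", None
    start = i5 + len(a5)
    i3 = read.find(a3, start)
    if i3 < 0:
        return "anchor_fail", None
    if i3 - start != INSERT_LENGTH:
        return "frame_fail", None
    return "ok", read[start:i3]


def decode_variant(insert: str) -> ReadDecodeResult:
    """Translate a 12-nt insert to a library variant.

    Stop codons and unreadable codons (non-ACGT) reject as ``codon_fail``;
    a position-3 codon outside the ACC/AGC design rejects as ``off_design``.
    """
    if len(insert) != INSERT_LENGTH:
        raise ValueError("insert must be exactly 12 nt")
    insert = insert.upper()
    residues = []
    for i in range(0, INSERT_LENGTH, 3):
        aa = translate_codon(insert[i : i + 3])
        if aa is None or aa == "*":
            return ReadDecodeResult("codon_fail")
        residues.append(aa)
    if insert[3:6] not in POSITION3_CODONS:
        return ReadDecodeResult("off_design")
    return ReadDecodeResult("valid", "".join(residues))


def decode_read(
    read: str, anchors: tuple[str, str] = DEFAULT_ANCHORS
) -> ReadDecodeResult:
    """Full per-read pipeline: anchor framing then codon decoding."""
    status, insert = extract_variable_region(read, anchors)
    if status != "ok":
        return ReadDecodeResult(status)
    return decode_variant(insert)


def _iter_fastq_sequences(path: str | Path):
    """Sequence lines of a 4-line FASTQ, plain or gzipped."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip()
            elif i % 4 == 0 and line and not line.startswith("@"):
                raise ValueError(f"{path} is not 4-line FASTQ (record {i // 4})")


def tally_counts(
    fastq_by_sample: dict[str, str | Path],
    anchors: tuple[str, str] = DEFAULT_ANCHORS,
) -> CountMatrix:
    """Count reads per variant for every sample's FASTQ.

    ``fastq_by_sample`` maps sample id -> FASTQ path (gz or plain).  Counts
    cover the full design space (zeros included); the QC table partitions
    each sample's reads over valid / anchor_fail / frame_fail / codon_fail /
    off_design.
    """
    variants = enumerate_library()
    v_index = {v: i for i, v in enumerate(variants)}
    counts = {}
    qc_rows = {}
    for sample, path in fastq_by_sample.items():
        col = np.zeros(len(variants), dtype=np.int64)
        qc = dict.fromkeys(QC_CATEGORIES, 0)
        for seq in _iter_fastq_sequences(path):
            res = decode_read(seq, anchors)
            qc[res.outcome] += 1
            if res.outcome == "valid":
                col[v_index[res.variant]] += 1
        counts[sample] = col
        qc_rows[sample] = qc
    counts_df = pd.DataFrame(counts, index=pd.Index(variants, name="variant"))
    qc_df = pd.DataFrame.from_dict(qc_rows, orient="index")[list(QC_CATEGORIES)]
    return CountMatrix(counts=counts_df, qc=qc_df)
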