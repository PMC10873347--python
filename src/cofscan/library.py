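"""The cofilin N-terminal variant library: design space, codons, translation.

The library randomizes residues 2, 4 and 5 of human cofilin-1 to all twenty
canonical amino acids while the phosphoacceptor at position 3 is either Ser
or Thr, giving 20^3 x 2 = 16,000 unique four-residue sequences.  Variants are
represented throughout the package as plain 4-character strings over the
one-letter amino-acid alphabet, ordered positions 2-3-4-5.

At the DNA level the variable region is 12 nt (four codons).  Position 3 is
encoded strictly by an ACC (Thr) / AGC (Ser) codon mixture; the remaining
positions use one fixed codon per residue (the physical oligo pool's
per-position codon usage is not public, so a documented stand-in table is
used for simulation; decoding accepts any standard-code codon).
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

#: One-letter amino-acid alphabet, alphabetical.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Residue positions covered by the variable region (cofilin numbering).
POSITIONS = (2, 3, 4, 5)

#: Allowed phosphoacceptor residues at position 3.
PHOSPHOACCEPTORS = "ST"

#: Codons permitted at position 3 in the oligo design.
POSITION3_CODONS = {"ACC": "T", "AGC": "S"}

LIBRARY_SIZE = 20 * 2 * 20 * 20

#: Fixed sense codon per residue used when writing simulated reads
#: (common yeast codons; position 3 overridden by the ACC/AGC rule).
SENSE_CODONS = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTG",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)

#: Default amplicon anchors flanking the 12-nt variable region.  The 5'
#: anchor ends at the initiator-Met codon; the 3' anchor begins at residue 6.
DEFAULT_ANCHORS = ("GGTGCAGGAGCCATG", "GCTGTTTCTGATGGT")

#: Wild-type human cofilin-1 N-terminal sequence (residues 2-5).
WT_VARIANT = "ASGV"


@lru_cache(maxsize=1)
def enumerate_library() -> tuple[str, ...]:
    """All 16,000 design-space variants in lexicographic order.

    The order is deterministic and used as the canonical variant index of
    every count matrix and score table in the package.
    """
    return tuple(
        a2 + a3 + a4 + a5
        for a2 in AA_ALPHABET
        for a3 in PHOSPHOACCEPTORS
        for a4 in AA_ALPHABET
        for a5 in AA_ALPHABET
    )


def is_design_variant(variant: str) -> bool:
    """True if ``variant`` is one of the 16,000 library members."""
    return (
        len(variant) == 4
        and all(aa in AA_ALPHABET for aa in variant)
        and variant[1] in PHOSPHOACCEPTORS
    )


def validate_variant(variant: str) -> str:
    if not is_design_variant(variant):
        raise ValueError(
            f"{variant!r} is not a library variant (4 residues, "
            f"position 3 in {set(PHOSPHOACCEPTORS)})"
        )
    return variant


def encode_variant(variant: str, codon_table: dict[str, str] | None = None) -> str:
    """12-nt DNA insert for a variant, position 3 forced to ACC/AGC."""
    validate_variant(variant)
    table = SENSE_CODONS if codon_table is None else codon_table
    missing = [aa for aa in AA_ALPHABET if aa not in table]
    if missing:
        raise ValueError(f"codon table missing residues: {missing}")
    pos3 = "ACC" if variant[1] == "T" else "AGC"
    return table[variant[0]] + pos3 + table[variant[2]] + table[variant[3]]


def translate_codon(codon: str) -> str | None:
    """One-letter residue for a sense codon, '*' for stop, None if invalid."""
    codon = codon.upper()
    if codon in _CODON_TO_AA:
        return _CODON_TO_AA[codon]
    if codon in _STOP_CODONS:
        return "*"
    return None
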