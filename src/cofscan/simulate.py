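"""Synthetic screen and assay generator with known ground truth.

Every downstream stage of the pipeline (counting, scoring, quadrant calls,
sequence statistics, curve fits) can be exercised against data whose true
fitness landscape or true curve parameters are known.  The growth model is
deterministic exponential competition in pooled doublings: after ``d``
doublings a variant with relative growth rate ``w`` changes abundance in
proportion to ``2**(w*d)``, and frequencies renormalize.  Sequencing is a
multinomial draw at finite depth; reads are emitted as anchored 12-nt
amplicons with optional uniform substitution errors.

Biochemical assays are generated from the same parametric forms the fitting
module estimates: a four-parameter logistic in cofilin dose for the pyrene
quench binding assay, and Michaelis-Menten initial rates for the radiolabel
kinase assay.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ScreenDesign
from .library import (
    DEFAULT_ANCHORS,
    LIBRARY_SIZE,
    SENSE_CODONS,
    encode_variant,
    enumerate_library,
)

# ---------------------------------------------------------------------------
# Fitness landscapes
# ---------------------------------------------------------------------------

#: Position-5 residues treated as function-compatible (aliphatic or
#: beta-branched side chains).
FAVORED_POS5 = set("AVILMT")
#: Charged residues (plus proline) — near-null at position 5.
CHARGED = set("DEKRH")
#: Position-4 residues compatible with function (Gly plus hydrophobics).
TOLERATED_POS4 = set("GAVILMFWY")
#: Bulky hydrophobic position-4 residues that uncouple phosphorylation from
#: inhibition: Ser3 variants carrying them stay functional under the kinase.
BULKY_POS4 = set("LFW")

FITNESS_PRESETS = ("uniform", "paper-like", "user-table")


@dataclass(frozen=True)
class FitnessMap:
    """Ground-truth relative growth rates for all 16,000 variants.

    ``w_glu`` is the growth rate with the kinase repressed (glucose),
    ``w_gal`` with LIMK1 induced (galactose), both in doublings per
    wild-type doubling.  ``w_gal <= w_glu`` holds for every variant that is
    phosphorylatable and inhibitable under the preset rules.
    """

    variants: tuple[str, ...]
    w_glu: np.ndarray
    w_gal: np.ndarray
    preset: str
    seed: int | None = None

    def __post_init__(self):
        if not (len(self.variants) == len(self.w_glu) == len(self.w_gal)):
            raise ValueError("variant/fitness length mismatch")
        if np.any(self.w_glu < 0) or np.any(self.w_gal < 0):
            raise ValueError("fitness values must be non-negative")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"w_glu": self.w_glu, "w_gal": self.w_gal},
            index=pd.Index(self.variants, name="variant"),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.as_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FitnessMap":
        df = pd.read_csv(path, sep="\t", index_col="variant")
        return cls(
            variants=tuple(df.index),
            w_glu=df["w_glu"].to_numpy(float),
            w_gal=df["w_gal"].to_numpy(float),
            preset="user-table",
        )


def _paper_like_w(variants: tuple[str, ...], rng: np.random.Generator):
    """Feature-keyed fitness rules emulating the screen's selection pattern.

    Position 5 dominates (aliphatic/beta-branched required; charged or Pro
    near-null), position 4 is intermediate (Gly and hydrophobics tolerated,
    charged/Pro strongly deleterious), position 2 is nearly indiscriminate.
    Under kinase induction, only Ser3 variants lacking a bulky position-4
    residue are inhibited; Thr3 variants are not phosphorylated.
    """
    f5 = np.array(
        [1.0 if v[3] in FAVORED_POS5 else 0.05 if v[3] in CHARGED | {"P"} else 0.45
         for v in variants]
    )
    f4 = np.array(
        [1.0 if v[2] in TOLERATED_POS4 else 0.15 if v[2] in CHARGED | {"P"} else 0.55
         for v in variants]
    )
    f2 = np.array([0.85 if v[0] in CHARGED | {"P"} else 1.0 for v in variants])
    w_glu = f2 * f4 * f5
    # biological scatter around the class means (CV ~5% of WT fitness)
    w_glu = np.clip(w_glu + rng.normal(0.0, 0.05, size=len(variants)), 0.0, None)
    inhibited = np.array(
        [v[1] == "S" and v[2] not in BULKY_POS4 for v in variants]
    )
    w_gal = np.where(inhibited, 0.15 * w_glu, w_glu)
    return w_glu, w_gal


def build_fitness_map(
    preset: str,
    seed: int | None = None,
    table: pd.DataFrame | None = None,
) -> FitnessMap:
    """Ground-truth fitness landscape for the full design space.

    Parameters
    ----------
    preset : "uniform" (all variants neutral, w_glu = w_gal = 1),
        "paper-like" (feature-keyed rules above, stochastic scatter), or
        "user-table" (explicit ``table`` with columns w_glu/w_gal indexed by
        variant).
    seed : required for stochastic presets; the map is deterministic given
        (preset, seed).
    """
    if preset not in FITNESS_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {FITNESS_PRESETS}")
    variants = enumerate_library()
    if preset == "uniform":
        ones = np.ones(LIBRARY_SIZE)
        return FitnessMap(variants, ones, ones.copy(), preset, seed)
    if preset == "user-table":
        if table is None:
            raise ValueError("user-table preset requires a fitness table")
        df = table.set_index("variant") if "variant" in table.columns else table
        df = df.reindex(variants)
        if df[["w_glu", "w_gal"]].isna().any().any():
            raise ValueError("fitness table must cover all 16,000 variants")
        return FitnessMap(
            variants, df["w_glu"].to_numpy(float), df["w_gal"].to_numpy(float), preset
        )
    if seed is None:
        raise ValueError("paper-like preset is stochastic; a seed is required")
    rng = np.random.default_rng(seed)
    w_glu, w_gal = _paper_like_w(variants, rng)
    return FitnessMap(variants, w_glu, w_gal, preset, seed)


# ---------------------------------------------------------------------------
# Serial-dilution competitive growth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbundanceTrajectory:
    """Per-sample variant frequencies for every (replicate, condition,
    timepoint) of a screen design.  Columns are sample ids; every column
    sums to 1."""

    frequencies: pd.DataFrame
    design: ScreenDesign

    def sample(self, replicate: int, condition: str, timepoint: str) -> pd.Series:
        return self.frequencies[self.design.sample_id(replicate, condition, timepoint)]


def grow(freq: np.ndarray, w: np.ndarray, doublings: float) -> np.ndarray:
    """Deterministic competition: freq_v -> freq_v * 2**(w_v * d), renormalized."""
    if doublings < 0:
        raise ValueError("doublings must be non-negative")
    out = freq * np.exp2(w * doublings)
    total = out.sum()
    if total <= 0:
        raise ValueError("population went extinct")
    return out / total


def simulate_serial_growth(
    fitness: FitnessMap,
    design: ScreenDesign | None = None,
    initial: np.ndarray | None = None,
    seed: int | None = None,
) -> AbundanceTrajectory:
    """Simulate the pooled screen for every replicate and condition.

    T0 frequencies are shared between the two conditions of a replicate
    (the culture is split at T0); selection then acts with ``w_glu`` or
    ``w_gal`` over ``doublings_per_cycle`` pooled doublings per cycle.  If
    ``initial`` is omitted, each replicate starts from a seeded lognormal
    jitter (CV ~10%) around the uniform pool, mimicking replicate-to-replicate
    variation in library representation; with an explicit ``initial`` and no
    bottleneck the trajectory is fully deterministic.
    """
    design = design or ScreenDesign()
    n = len(fitness.variants)
    rng = np.random.default_rng(seed)
    if initial is not None:
        initial = np.asarray(initial, dtype=float)
        if initial.shape != (n,):
            raise ValueError("initial frequencies must match the variant index")
        if np.any(initial < 0):
            raise ValueError("initial frequencies must be non-negative")
        s = initial.sum()
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError("initial frequencies must sum to 1")
        initial = initial / s

    w_by_condition = {"glucose": fitness.w_glu, "galactose": fitness.w_gal}
    cols: dict[str, np.ndarray] = {}
    for r in range(1, design.n_replicates + 1):
        if initial is None:
            f0 = np.exp(rng.normal(0.0, 0.1, size=n))
            f0 /= f0.sum()
        else:
            f0 = initial.copy()
        for cond in design.conditions:
            w = w_by_condition[cond]
            freq = f0.copy()
            cols[design.sample_id(r, cond, design.timepoints[0])] = freq
            for tp in design.timepoints[1:]:
                if design.bottleneck_cells is not None:
                    kept = rng.multinomial(design.bottleneck_cells, freq)
                    total = kept.sum()
                    if total == 0:
                        raise ValueError("bottleneck extinguished the population")
                    freq = kept / total
                freq = grow(freq, w, design.doublings_per_cycle)
                cols[design.sample_id(r, cond, tp)] = freq

    df = pd.DataFrame(cols, index=pd.Index(fitness.variants, name="variant"))
    return AbundanceTrajectory(frequencies=df, design=design)


def sample_sequencing_reads(
    trajectory: AbundanceTrajectory,
    depth: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Multinomial read counts per sample at finite sequencing depth.

    Returns an integer DataFrame (variant x sample) whose column sums equal
    ``depth`` exactly.
    """
    design = trajectory.design
    depth = design.depth if depth is None else depth
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(seed)
    counts = {}
    for col in trajectory.frequencies.columns:
        p = trajectory.frequencies[col].to_numpy(float)
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"frequencies of {col} are not normalized")
        counts[col] = rng.multinomial(depth, p / total)
    return pd.DataFrame(counts, index=trajectory.frequencies.index)


# ---------------------------------------------------------------------------
# Amplicon FASTQ emission
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_substitutions(seqs: np.ndarray, error_rate: float, rng) -> np.ndarray:
    """Uniform per-base substitutions on a (n_reads, read_len) uint8 array."""
    if error_rate == 0:
        return seqs
    mask = rng.random(seqs.shape) < error_rate
    if not mask.any():
        return seqs
    # draw a base different from the original: offset 1-3 in ACGT order
    idx = np.searchsorted(_BASES, seqs[mask])
    offsets = rng.integers(1, 4, size=mask.sum())
    seqs = seqs.copy()
    seqs[mask] = _BASES[(idx + offsets) % 4]
    return seqs


def emit_amplicon_fastq(
    counts: pd.DataFrame,
    out_dir: str | Path,
    codon_table: dict[str, str] | None = None,
    anchors: tuple[str, str] = DEFAULT_ANCHORS,
    error_rate: float = 0.0,
    seed: int | None = None,
    gzipped: bool = True,
) -> dict[str, Path]:
    """Write one FASTQ per sample: 5' anchor + 12-nt insert + 3' anchor.

    One read per counted molecule, constant Phred+33 quality 'I', optional
    uniform substitution errors.  At ``error_rate`` 0 the files round-trip
    exactly through :func:`cofscan.counting.tally_counts`.
    """
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    if not anchors[0] or not anchors[1]:
        raise ValueError("anchors must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    table = SENSE_CODONS if codon_table is None else codon_table
    templates = np.array(
        [
            np.frombuffer(
                (anchors[0] + encode_variant(v, table) + anchors[1]).encode(), np.uint8
            )
            for v in counts.index
        ]
    )
    read_len = templates.shape[1]
    qual = "I" * read_len

    paths: dict[str, Path] = {}
    suffix = ".fastq.gz" if gzipped else ".fastq"
    for sample in counts.columns:
        c = counts[sample].to_numpy()
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        reads = _apply_substitutions(
            np.repeat(templates, c, axis=0), error_rate, rng
        )
        path = out_dir / f"{sample}{suffix}"
        opener = gzip.open if gzipped else open
        with opener(path, "wt") as fh:
            for i, row in enumerate(reads):
                fh.write(
                    f"@{sample}:{i}\n{row.tobytes().decode()}\n+\n{qual}\n"
                )
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# Biochemical assay synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingCurveSpec:
    """True parameters for a pyrene-quench actin binding titration.

    ``k_half`` is the cofilin concentration (uM) at half-maximal occupancy;
    the fluorescence signal starts at ``top`` (unquenched actin alone) and
    descends to ``bottom`` (saturated cofilactin).  Noise is multiplicative
    lognormal with coefficient of variation ``noise_cv``.
    """

    k_half: float
    hill: float = 1.5
    top: float = 1.0
    bottom: float = 0.0
    concentrations: tuple[float, ...] | None = None
    noise_cv: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.k_half <= 0 or self.hill <= 0:
            raise ValueError("k_half and hill slope must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.concentrations is not None and any(
            c < 0 for c in self.concentrations
        ):
            raise ValueError("concentrations must be non-negative")

    def default_concentrations(self) -> np.ndarray:
        """Two-fold serial dilutions bracketing k_half, plus a zero dose."""
        doses = self.k_half * np.exp2(np.arange(5, -6.0, -1))
        return np.concatenate([[0.0], doses[::-1]])


def logistic_response(conc, k_half, hill, top, bottom):
    """Four-parameter logistic in dose; midpoint at ``k_half`` by construction."""
    conc = np.asarray(conc, dtype=float)
    frac = np.zeros_like(conc)
    pos = conc > 0
    frac[pos] = conc[pos] ** hill / (k_half**hill + conc[pos] ** hill)
    return top + (bottom - top) * frac


def simulate_binding_curve(spec: BindingCurveSpec) -> pd.DataFrame:
    """Concentration-signal table for a binding titration.

    Noiseless signal at zero dose equals the top plateau and is monotone
    non-increasing in dose; a downstream dose-response fit recovers the spec
    parameters exactly when ``noise_cv`` is 0.
    """
    conc = (
        np.asarray(spec.concentrations, dtype=float)
        if spec.concentrations is not None
        else spec.default_concentrations()
    )
    signal = logistic_response(conc, spec.k_half, spec.hill, spec.top, spec.bottom)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        signal = signal * rng.lognormal(-sigma**2 / 2, sigma, size=signal.shape)
    return pd.DataFrame({"concentration_uM": conc, "signal": signal})


#: Binding presets: measured half-maximal binding of purified variants
#: against 1 uM polymerized pyrene-actin.
BINDING_PRESETS = {
    "WT": BindingCurveSpec(k_half=0.61),
    "A2L": BindingCurveSpec(k_half=0.53),
    "A2D": BindingCurveSpec(k_half=1.5),
    "S3D": BindingCurveSpec(k_half=4.7),
    "G4A": BindingCurveSpec(k_half=3.2),
    "G4F": BindingCurveSpec(k_half=1.0),
    "G4K": BindingCurveSpec(k_half=3.5),
    "V5M": BindingCurveSpec(k_half=0.48),
}


@dataclass(frozen=True)
class KinaseAssaySpec:
    """True parameters for a radiolabel kinase time course.

    Product accumulates linearly at the Michaelis-Menten initial rate
    v = kcat * [E] * [S] / (KM + [S]); the default grid is seven substrate
    concentrations spanning 50 to 0.5 uM with 2 nM enzyme, sampled at 5 and
    10 min.  ``standards`` are gamma-32P spots (nCi) imaged alongside.
    """

    kcat: float  # s^-1
    km: float  # uM
    enzyme_nM: float = 2.0
    substrate_uM: tuple[float, ...] = tuple(np.geomspace(50.0, 0.5, 7).round(4))
    timepoints_min: tuple[float, ...] = (5.0, 10.0)
    noise_cv: float = 0.0
    standards_nCi: tuple[float, ...] = (2.5, 5.0, 10.0)
    signal_per_nCi: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.kcat <= 0 or self.km <= 0 or self.enzyme_nM <= 0:
            raise ValueError("kcat, KM and enzyme concentration must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if any(s < 0 for s in self.substrate_uM):
            raise ValueError("substrate concentrations must be non-negative")
        if list(self.timepoints_min) != sorted(self.timepoints_min):
            raise ValueError("timepoints must be increasing")

    def rate_uM_per_s(self, substrate_uM: np.ndarray) -> np.ndarray:
        s = np.asarray(substrate_uM, dtype=float)
        e_uM = self.enzyme_nM * 1e-3
        return self.kcat * e_uM * s / (self.km + s)


def simulate_kinase_timecourse(
    spec: KinaseAssaySpec, with_standards: bool = True
) -> dict[str, pd.DataFrame]:
    """Phosphate-incorporation table (and optional standard-curve points).

    Raises if any requested timepoint would push product beyond 10% of
    substrate, outside the initial-rate regime the linear model assumes.
    """
    s = np.asarray(spec.substrate_uM, dtype=float)
    t_s = np.asarray(spec.timepoints_min, dtype=float) * 60.0
    v = spec.rate_uM_per_s(s)
    product = np.outer(t_s, v)  # (time, substrate), uM
    nonzero = s > 0
    if np.any(product[:, nonzero] > 0.1 * s[nonzero]):
        raise ValueError(
            "timepoints violate the initial-rate bound (product > 10% substrate)"
        )
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        product = product * rng.lognormal(-sigma**2 / 2, sigma, size=product.shape)
    rows = [
        {
            "substrate_uM": s[j],
            "time_min": spec.timepoints_min[i],
            "product_uM": product[i, j],
        }
        for j in range(len(s))
        for i in range(len(t_s))
    ]
    out = {"timecourse": pd.DataFrame(rows)}
    if with_standards:
        out["standards"] = pd.DataFrame(
            {
                "nCi": spec.standards_nCi,
                "signal": [spec.signal_per_nCi * x for x in spec.standards_nCi],
            }
        )
    return out


#: Kinase presets: steady-state parameters for LIMK1 phosphorylation of
#: purified cofilin (2 nM kinase domain, 30 C).
KINETIC_PRESETS = {
    "WT": KinaseAssaySpec(kcat=0.20, km=9.0),
    "G4F": KinaseAssaySpec(kcat=0.55, km=12.0),
}
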