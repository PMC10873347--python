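# Methods

This note documents the models implemented in `cofscan`, the parameter
choices that matter, and what the synthetic data generator does and does
not emulate.

## The library

The design space is the set of 4-residue N-terminal tails (cofilin
positions 2–5) with positions 2, 4 and 5 free over the 20 canonical amino
acids and position 3 restricted to the phosphoacceptors Ser/Thr:
20³ × 2 = 16,000 variants, enumerated once in lexicographic order and used
as the canonical index of every count and score table.  At the DNA level
the variable region is 12 nt; position 3 is encoded strictly by ACC (Thr)
or AGC (Ser).  The physical oligo pool's codon usage at the other
positions is not public, so the simulator writes one fixed, documented
sense codon per residue (`SENSE_CODONS`); decoding accepts any
standard-code codon, so this choice affects emission only, not counting.

## Competitive-growth model

Selection is modeled as deterministic exponential competition in pooled
doublings: after `d` doublings a variant with relative growth rate `w`
(doublings per wild-type doubling) changes abundance in proportion to
`2^(w·d)`, and frequencies renormalize.  For two variants this reduces to
the logistic closed form, which the test suite checks to 1e-12.  Each
growth-and-dilution cycle spans 3.5 pooled doublings — the culture window
OD 0.1 → 1–2 corresponds to log2(10)–log2(20) ≈ 3.3–4.3 doublings — so the
three cycles after T0 span ~10.5 doublings and the function contrast
(T0→T2) ~7.  Dilution bottlenecks are real but small relative to
sequencing noise at ≥1000-fold variant coverage, so binomial bottleneck
resampling is implemented but off by default (`bottleneck_cells=None`).
T0 is sampled before the culture splits; both conditions of a replicate
share T0 frequencies, and replicates differ by a seeded lognormal jitter
(CV ≈ 10%) around the uniform pool unless explicit initial frequencies
are given.

The `paper-like` fitness preset keys `w_glu` to residue classes:
position 5 dominant (aliphatic/β-branched ≈ 1, charged or Pro ≈ 0.05,
others 0.45), position 4 intermediate (Gly and hydrophobics 1, charged/Pro
0.15, others 0.55), position 2 nearly neutral (0.85 for charged/Pro),
multiplied and perturbed by N(0, 0.05) scatter, clipped at zero.  Under
kinase induction, `w_gal = 0.15·w_glu` for variants that are both
phosphorylatable (Ser3) and inhibitable (position 4 not Leu/Phe/Trp —
bulky residues uncouple phosphorylation from inhibition); all other
variants keep `w_gal = w_glu`.  The 0.15 residual reflects partial
inhibition under full-length LIMK1 rather than complete growth arrest.
These rules are a caricature with the right class structure, not a fit to
any measured landscape; the fraction of functional variants called
sensitive (~1/3 in the worked example) emerges from them.

## Sequencing and read emission

Sequencing is a multinomial draw per sample at fixed depth (default 10⁶
reads/sample, ≥60× mean per-variant coverage).  Reads are emitted one per
counted molecule as 5′ anchor + 12-nt insert + 3′ anchor with constant
Phred+33 quality `I`; errors are uniform per-base substitutions only.
Indels are not modeled: in a 12-nt amplicon core they would break the
exact anchor frame and be rejected, so they only inflate `frame_fail`.
PCR amplification bias, plasmid copy-number variation and induction lag
are not modeled either — recovery results on synthetic screens therefore
show correctness of the scoring pipeline, not robustness to those
real-data artifacts.

## Counting

Anchors are matched exactly (the first 5′ anchor occurrence, then the
first 3′ occurrence after it); a 12-nt gap is decoded codon-wise by the
standard genetic code.  Every read lands in exactly one QC category —
`valid`, `anchor_fail`, `frame_fail`, `codon_fail` (stop or unreadable
codon), `off_design` (position-3 codon outside ACC/AGC) — and the
categories partition the read total per sample.  Frequency denominators
use valid on-design reads only.  Count matrices always carry all 16,000
variants, zeros included.

## Scoring

Relative representation is `(count + pc) / Σ(count + pc)` with pseudocount
`pc = 0.5` by default: the zero-count policy of the original analysis is
unstated, and 0.5 keeps log-ratios finite with minimal shrinkage.  With
`pc = 0`, zero-count variants are flagged invalid (NaN) and excluded from
means and ranking rather than propagated as infinities.  Scores are log2
ratios of relative representation — function: glucose T0→T2; LIMK axes:
T1→T3 in glucose and in galactose — averaged as the mean of per-replicate
log2 ratios (not the log of mean ratios).  Ranks descend on the function
mean with ties broken lexicographically by variant string, making repeated
runs bit-identical.  The enriched set uses strict `mean > 0`.

## Quadrant calls

Functional = LIMK-axis glucose mean > 0; sensitive = functional AND
galactose mean < 0; a galactose tie counts as resistant so "sensitive"
always means strict depletion.  Axis thresholds sit at the origin, with a
configurable symmetric margin for noise-robust calling (default 0).  The
glucose T1→T3 axis gates "functional" because that is the axis the
quadrant plane plots; the T0→T2 enriched flag is carried alongside in the
score table for the alternative gating.

## Positional statistics

Heat-map cells average the **log2** fold change over every sequence
carrying a residue at a position (800 sequences at positions 2/4/5, 8000
at position 3); a linear-fold option exists but log2 is the default for
consistency with the score tables.  Distribution summaries report
median/quartiles/deciles with linear interpolation between order
statistics.

Logo heights are signed exact binomial tails against the design
composition (1/20 at positions 2/4/5, 1/2 at position 3):
`-log10 P(X ≥ k)` when a residue is at or above expectation,
`+log10 P(X ≤ k)` (negative) below it, no normal approximation, with the
tail probability floored at the smallest positive double so heights stay
finite.  The Bonferroni divisor defaults to the 62 tested residue-position
cells; observed-T0 backgrounds and other divisors are arguments, since
logo conventions vary between tools and datasets.

Covariation compares observed joint residue-pair counts in a selected set
with `N·p_i(a)·p_j(b)`, marginals taken from the selected set itself (the
question is linkage *within* the set; a library-composition background is
an option).  P-values are exact binomial, two-sided by tail doubling
(`min(1, 2·min(lower, upper))`), which is slightly conservative but
vectorizes over the full residue grid; Bonferroni runs over all tested
cells.  Because marginals are estimated from the same set, the binomial
null is additionally conservative, and simulated independent sets produce
family-wise false-positive rates well below α.  Cells with expected counts
below a configurable floor, or zero observations, carry undefined log2
ratios (NaN).

## Binding fits

"Sigmoidal dose-response" is implemented as the four-parameter
variable-slope logistic on dose, `S(C) = s0 + (sinf − s0)·C^h/(K^h + C^h)`,
with K fit on a log10 scale for conditioning.  K is the half-maximal
midpoint by construction and is read as K₀.₅; the slope is a nuisance
parameter, not a mechanistic cooperativity estimate (lattice-binding
models are out of scope).  Initial guesses: plateaus from the signals at
the dose extremes, K from the interpolated half-max crossing, h = 1.
Because the confidence-interval method of the original analysis is
unstated, K₀.₅ intervals come from a seeded case-resampling bootstrap
(default n = 1000, 95% percentile), with refits warm-started at the
full-data optimum.  Plateaus are fit per curve, not shared across
variants.  The fit is equivariant to rescaling all signals.  Simulated
titrations default to two-fold serial dilutions bracketing K₀.₅ (11
doses plus a zero-dose point) with multiplicative lognormal noise.

## Kinase fits

Initial rates come from least squares of product on time through the
origin over the time course (5 and 10 min by default); points where
product exceeds 10% of substrate are flagged as outside the initial-rate
regime.  The γ-³²P standard curve (2.5/5/10 nCi) is a least-squares line
through the origin converting densitometry signal to absolute product.
Michaelis–Menten parameters are estimated by nonlinear least squares on
`v = kcat·[E]·[S]/(K_M+[S])` with residuals normalized to the maximum
rate (absolute rates are ~1e-4 µM/s, far below the optimizer's default
termination scales) and weighted by 1/rate, the standard choice when
measurement error is proportional to signal as it is for densitometry.
95% CIs use the t distribution with n−2 degrees of freedom.  Two
substrate concentrations determine the parameters exactly — equal to the
Lineweaver–Burk closed form, used as a test oracle — but leave no
residual degrees of freedom, so SEs are NaN and a warning is raised below
three concentrations.

## Problem sizes and what the tests show

Recovery tests simulate full 16,000-variant screens (3 replicates, 10⁶
reads/sample); curve-fit recovery uses 100 seeded simulations per preset
at CV 5% with 200 bootstrap refits per binding curve; the covariation
null calibration uses 200 independent sets of 500 sequences.  The
acceptance script reports median recovered k_cat over 100 simulated
assays per kinetic preset.  Passing these checks demonstrates estimator
correctness and calibration under the generator's assumptions
(multiplicative noise, no PCR bias, exponential competition); they do not
certify performance on real screens, where bottlenecks, amplification
bias and culture-condition drift add structure the generator omits.

## Known limitations

* Enrichment is a two-timepoint log-ratio, not a regression over all
  timepoints; no variance shrinkage across variants.
* No per-variant significance testing of depletion in quadrant calls.
* Logos and covariation treat sequences as exchangeable draws; they do
  not model the selection process that produced the set.
* The codon table and anchors are simulator conventions, not the
  laboratory amplicon design.
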