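"""Generator behaviour: fitness presets, competitive growth, sequencing,
FASTQ emission, and synthetic biochemical curves."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

import cofscan as cs
from cofscan.simulate import grow


# ---- fitness presets -------------------------------------------------------


def test_uniform_preset_is_neutral():
    fm = cs.build_fitness_map("uniform")
    assert np.all(fm.w_glu == 1.0) and np.all(fm.w_gal == 1.0)


def test_paper_like_is_deterministic_given_seed():
    a = cs.build_fitness_map("paper-like", seed=1)
    b = cs.build_fitness_map("paper-like", seed=1)
    assert np.array_equal(a.w_glu, b.w_glu) and np.array_equal(a.w_gal, b.w_gal)


def test_paper_like_inhibits_ser3_but_not_thr3():
    fm = cs.build_fitness_map("paper-like", seed=1).as_frame()
    assert fm.loc["ASGV", "w_gal"] < fm.loc["ASGV", "w_glu"]
    assert fm.loc["ATGV", "w_gal"] == fm.loc["ATGV", "w_glu"]
    # bulky position-4 residues uncouple Ser3 variants from inhibition
    assert fm.loc["ASLV", "w_gal"] == fm.loc["ASLV", "w_glu"]


def test_kinase_inhibition_never_raises_fitness():
    fm = cs.build_fitness_map("paper-like", seed=5)
    assert np.all(fm.w_gal <= fm.w_glu + 1e-12)


def test_preset_errors():
    with pytest.raises(ValueError, match="unknown preset"):
        cs.build_fitness_map("bogus")
    with pytest.raises(ValueError, match="seed"):
        cs.build_fitness_map("paper-like")


def test_fitness_tsv_roundtrip(tmp_path):
    fm = cs.build_fitness_map("paper-like", seed=2)
    path = tmp_path / "fitness.tsv"
    fm.to_tsv(path)
    back = cs.FitnessMap.from_tsv(path)
    assert np.allclose(back.w_glu, fm.w_glu) and np.allclose(back.w_gal, fm.w_gal)


# ---- competitive growth ----------------------------------------------------


def test_two_variant_competition_closed_form():
    f = grow(np.array([0.5, 0.5]), np.array([1.0, 0.0]), 1.0)
    assert np.allclose(f, [2 / 3, 1 / 3], atol=1e-15)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    w=st.lists(st.floats(0.0, 2.0), min_size=2, max_size=6),
    d=st.floats(0.1, 10.0),
)
def test_growth_matches_logistic_closed_form(w, d):
    """freq_v(d) = f0 2^(w_v d) / sum over the pool, for any pool."""
    w = np.asarray(w)
    f0 = np.full(len(w), 1 / len(w))
    out = grow(f0, w, d)
    expected = np.exp2(w * d) / np.exp2(w * d).sum()
    assert np.allclose(out, expected, atol=1e-12)
    assert abs(out.sum() - 1) < 1e-12


def test_equal_fitness_leaves_frequencies_unchanged():
    fm = cs.build_fitness_map("uniform")
    init = np.random.default_rng(0).dirichlet(np.ones(cs.LIBRARY_SIZE))
    traj = cs.simulate_serial_growth(fm, initial=init)
    for col in traj.frequencies:
        assert np.allclose(traj.frequencies[col].to_numpy(), init, atol=1e-12)


def test_trajectory_frequencies_conserved(trajectory):
    sums = trajectory.frequencies.sum(axis=0)
    assert np.all(np.abs(sums - 1.0) < 1e-9)
    assert (trajectory.frequencies.to_numpy() >= 0).all()


def test_trajectory_deterministic_given_seed(fitness_map, design):
    a = cs.simulate_serial_growth(fitness_map, design, seed=7)
    b = cs.simulate_serial_growth(fitness_map, design, seed=7)
    pd.testing.assert_frame_equal(a.frequencies, b.frequencies)


def test_wt_depletes_under_kinase_while_thr3_persists(trajectory):
    """The Ser3 wild type falls between T1 and T3 under induction; its
    Thr3 counterpart does not (the resistant-variant pattern)."""
    wt_t1 = trajectory.sample(1, "galactose", "T1")["ASGV"]
    wt_t3 = trajectory.sample(1, "galactose", "T3")["ASGV"]
    thr_t1 = trajectory.sample(1, "galactose", "T1")["ATGV"]
    thr_t3 = trajectory.sample(1, "galactose", "T3")["ATGV"]
    assert wt_t3 < wt_t1
    assert thr_t3 >= thr_t1


# ---- sequencing ------------------------------------------------------------


def _single_sample_trajectory(freqs, design):
    df = pd.DataFrame({"s1": freqs})
    return cs.AbundanceTrajectory(frequencies=df, design=design)


def test_depth_zero_gives_all_zero_counts(trajectory):
    counts = cs.sample_sequencing_reads(trajectory, depth=0, seed=1)
    assert (counts.to_numpy() == 0).all()


def test_single_variant_pool_takes_all_reads(design):
    freqs = pd.Series(np.zeros(cs.LIBRARY_SIZE), index=cs.enumerate_library())
    freqs["ASGV"] = 1.0
    traj = _single_sample_trajectory(freqs, design)
    counts = cs.sample_sequencing_reads(traj, depth=10**6, seed=1)
    assert counts.loc["ASGV", "s1"] == 10**6
    assert counts["s1"].sum() == 10**6


def test_column_sums_equal_depth(trajectory):
    counts = cs.sample_sequencing_reads(trajectory, depth=50_000, seed=2)
    assert (counts.sum(axis=0) == 50_000).all()


def test_uniform_pool_counts_pass_chi_square(design):
    freqs = pd.Series(
        np.full(cs.LIBRARY_SIZE, 1 / cs.LIBRARY_SIZE), index=cs.enumerate_library()
    )
    traj = _single_sample_trajectory(freqs, design)
    counts = cs.sample_sequencing_reads(traj, depth=16_000_000, seed=3)
    stat, p = chisquare(counts["s1"].to_numpy())
    assert p >= 0.01


def test_doubling_depth_preserves_expected_frequencies(design):
    """Monte-Carlo mean frequency is depth-invariant (multinomial sampling
    is unbiased at any depth)."""
    freqs = pd.Series(
        [0.4, 0.3, 0.15, 0.1, 0.05], index=[f"v{i}" for i in range(5)]
    )
    traj = _single_sample_trajectory(freqs, design)
    means = {}
    for depth in (1000, 2000):
        acc = np.zeros(5)
        for seed in range(120):
            c = cs.sample_sequencing_reads(traj, depth=depth, seed=seed)
            acc += c["s1"].to_numpy() / depth
        means[depth] = acc / 120
    assert np.allclose(means[1000], means[2000], atol=0.01)
    assert np.allclose(means[1000], freqs.to_numpy(), atol=0.01)


def test_unnormalized_frequencies_rejected(design):
    freqs = pd.Series(np.full(cs.LIBRARY_SIZE, 2 / cs.LIBRARY_SIZE),
                      index=cs.enumerate_library())
    traj = _single_sample_trajectory(freqs, design)
    with pytest.raises(ValueError, match="not normalized"):
        cs.sample_sequencing_reads(traj, depth=100, seed=0)


# ---- FASTQ emission --------------------------------------------------------


def test_zero_counts_give_empty_fastq(tmp_path):
    counts = pd.DataFrame(
        {"s1": np.zeros(cs.LIBRARY_SIZE, dtype=int)}, index=cs.enumerate_library()
    )
    paths = cs.emit_amplicon_fastq(counts, tmp_path, gzipped=False)
    assert paths["s1"].read_text() == ""


def test_emitted_reads_use_design_codons(tmp_path):
    rng = np.random.default_rng(4)
    col = np.zeros(cs.LIBRARY_SIZE, dtype=int)
    col[rng.choice(cs.LIBRARY_SIZE, 50, replace=False)] = 3
    counts = pd.DataFrame({"s1": col}, index=cs.enumerate_library())
    paths = cs.emit_amplicon_fastq(counts, tmp_path, gzipped=False)
    lines = paths["s1"].read_text().splitlines()
    seqs = lines[1::4]
    assert len(seqs) == 150
    a5, a3 = cs.DEFAULT_ANCHORS
    for s in seqs:
        insert = s[len(a5): len(a5) + 12]
        assert s == a5 + insert + a3
        assert insert[3:6] in ("ACC", "AGC")  # phosphoacceptor codon design


def test_emit_rejects_bad_inputs(tmp_path):
    counts = pd.DataFrame({"s1": [1]}, index=["ASGV"])
    with pytest.raises(ValueError, match="anchors"):
        cs.emit_amplicon_fastq(counts, tmp_path, anchors=("", "AAA"))
    with pytest.raises(ValueError, match="error_rate"):
        cs.emit_amplicon_fastq(counts, tmp_path, error_rate=1.5)


# ---- biochemical curves ----------------------------------------------------


def test_binding_curve_plateaus_and_midpoint():
    spec = cs.BindingCurveSpec(k_half=0.61, top=0.9, bottom=0.1)
    curve = cs.simulate_binding_curve(spec)
    sig = curve.set_index("concentration_uM")["signal"]
    assert sig.loc[0.0] == pytest.approx(0.9)
    # monotone non-increasing with dose
    assert np.all(np.diff(sig.sort_index().to_numpy()) <= 1e-12)
    # dose = K_0.5 sits exactly midway between plateaus
    mid = cs.logistic_response(np.array([0.61]), 0.61, spec.hill, 0.9, 0.1)
    assert mid[0] == pytest.approx(0.5)


def test_binding_default_doses_bracket_k_half():
    spec = cs.BindingCurveSpec(k_half=0.61)
    doses = spec.default_concentrations()
    pos = doses[doses > 0]
    assert pos.min() < 0.61 < pos.max()
    # two-fold serial dilution series
    assert np.allclose(np.diff(np.log2(pos)), 1.0)


def test_binding_spec_validation():
    with pytest.raises(ValueError):
        cs.BindingCurveSpec(k_half=-1.0)
    with pytest.raises(ValueError):
        cs.BindingCurveSpec(k_half=1.0, hill=0.0)
    with pytest.raises(ValueError):
        cs.BindingCurveSpec(k_half=1.0, noise_cv=-0.1)


def test_kinase_timecourse_noiseless_linearity():
    spec = replace(
        cs.KINETIC_PRESETS["WT"], substrate_uM=(0.0, 5.0, 50.0)
    )
    tc = cs.simulate_kinase_timecourse(spec)["timecourse"]
    zero = tc[tc.substrate_uM == 0.0]
    assert (zero["product_uM"] == 0.0).all()
    five = tc[(tc.substrate_uM == 5.0)].set_index("time_min")["product_uM"]
    assert five.loc[10.0] == pytest.approx(2 * five.loc[5.0])


def test_kinase_standards_emitted():
    out = cs.simulate_kinase_timecourse(cs.KINETIC_PRESETS["WT"])
    assert list(out["standards"]["nCi"]) == [2.5, 5.0, 10.0]


def test_kinase_initial_rate_bound_enforced():
    spec = replace(cs.KINETIC_PRESETS["WT"], timepoints_min=(5.0, 10_000.0))
    with pytest.raises(ValueError, match="initial-rate"):
        cs.simulate_kinase_timecourse(spec)
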