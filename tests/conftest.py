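"""Shared fixtures: one fully simulated screen reused across test modules."""

import numpy as np
import pytest

import cofscan as cs


@pytest.fixture(scope="session")
def design():
    return cs.ScreenDesign()


@pytest.fixture(scope="session")
def fitness_map():
    return cs.build_fitness_map("paper-like", seed=11)


@pytest.fixture(scope="session")
def trajectory(fitness_map, design):
    return cs.simulate_serial_growth(fitness_map, design, seed=12)


@pytest.fixture(scope="session")
def screen_counts(trajectory):
    return cs.sample_sequencing_reads(trajectory, depth=1_000_000, seed=13)


@pytest.fixture(scope="session")
def screen_scores(screen_counts, design):
    return cs.score_screen(cs.CountMatrix.from_counts(screen_counts), design)


@pytest.fixture(scope="session")
def truth_scores(fitness_map, design):
    """Scores from the infinite-depth (deterministic) trajectory: the
    generator's ground truth propagated through the same scoring path."""
    det = cs.simulate_serial_growth(
        fitness_map, design, initial=np.full(cs.LIBRARY_SIZE, 1 / cs.LIBRARY_SIZE)
    )
    return cs.score_screen(det.frequencies, design, pseudocount=0.0)
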