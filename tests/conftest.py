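import numpy as np
import pytest

import seqrecode as sq


@pytest.fixture(scope="session")
def design():
    """A constraint-passing 14-sequence set found by the Monte-Carlo search."""
    seq_set, score, trace = sq.monte_carlo_search(n_samples=2000, rng_seed=1)
    return seq_set, score, trace


@pytest.fixture(scope="session")
def seq_set(design):
    return design[0]


@pytest.fixture(scope="session")
def schedule(seq_set):
    """The standard two-run, 36-trials-per-run schedule."""
    return sq.build_schedule(seq_set, rng_seed=2)


@pytest.fixture(scope="session")
def stationary_fits(schedule):
    return sq.sequential_optimal_models(schedule)


@pytest.fixture(scope="session")
def model_rdms(schedule, stationary_fits):
    models = sq.candidate_model_rdms(schedule, include_chunk=False)
    models["chunk"] = sq.chunk_rdm(schedule, fits=stationary_fits)
    return models


@pytest.fixture(scope="session")
def all_permutations():
    return sq.enumerate_space(allow_repeats=False)


@pytest.fixture(scope="session")
def full_space():
    return sq.enumerate_space(allow_repeats=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
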