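import numpy as np
import pytest

from progpath import simulate_blobs, simulate_branching_data, simulate_survival


@pytest.fixture(scope="session")
def bifurcation_small():
    """Moderate branching cohort without irrelevant features (fast geometry tests)."""
    matrix, truth = simulate_branching_data(
        n_samples=400, j_rel=10, j_irrel=0, noise_sd=0.08, seed=5
    )
    return matrix, truth


@pytest.fixture(scope="session")
def blobs4():
    """Four well-separated Gaussian blobs."""
    matrix, labels = simulate_blobs(n_per=100, c=4, separation=20.0, j=2, seed=7)
    return matrix.values, labels


@pytest.fixture(scope="session")
def survival_cohort():
    matrix, truth = simulate_branching_data(
        n_samples=120, j_rel=8, j_irrel=12, noise_sd=0.1, seed=3
    )
    clinical = simulate_survival(truth, noise_sd=0.5, censor_rate=0.2, seed=4)
    return matrix, truth, clinical


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
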