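import numpy as np
import pytest

from stressrank.pipeline import dominance_results, interaction_matrices
from stressrank.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default conditions, shared read-only."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrices(default_study):
    return interaction_matrices(default_study.events)


@pytest.fixture(scope="session")
def default_dominance(default_matrices):
    return dominance_results(default_matrices)


def random_win_matrix(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """A random non-negative win matrix with zero diagonal."""
    if n is None:
        n = int(rng.integers(3, 9))
    W = rng.integers(0, 12, size=(n, n)).astype(float)
    np.fill_diagonal(W, 0)
    return W
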