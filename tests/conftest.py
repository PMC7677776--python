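import numpy as np
import pytest

from iimpute import ExpressionMatrix, SimulationParams, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_dataset():
    """A small 3-group simulation used by pipeline-level tests."""
    params = SimulationParams(n_genes=300, n_cells=60, dropout_mid=3, seed=11)
    return simulate(params)


@pytest.fixture
def random_counts(rng):
    vals = rng.poisson(5.0, size=(40, 12)).astype(float)
    vals[0, :] += 1  # keep every library size positive
    return ExpressionMatrix(
        vals,
        [f"g{i}" for i in range(40)],
        [f"c{j}" for j in range(12)],
    )
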