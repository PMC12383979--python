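import numpy as np
import pytest

from seizegraph.graph import build_adjacency, normalized_scaled_laplacian
from seizegraph.model import ModelConfig, SeizureGraphModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_model_config():
    """A model small enough for fast forward/backward unit checks."""
    return ModelConfig(n_channels=5, n_features=8, n_timesteps=6,
                       n_blocks=1, K=3, gcn_channels=4, tcn_channels=4,
                       fc_hidden=8, seed=3)


@pytest.fixture(scope="session")
def small_graph():
    rng = np.random.default_rng(7)
    A = rng.random((5, 5))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    return normalized_scaled_laplacian(A)


@pytest.fixture
def small_model(small_model_config, small_graph):
    return SeizureGraphModel(small_model_config, small_graph)
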