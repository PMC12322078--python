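import numpy as np
import pytest

from netatrophy import SynthConfig, make_spatial_connectome
from netatrophy.network import WeightedNetwork


@pytest.fixture(scope="session")
def small_net() -> WeightedNetwork:
    """A 60-parcel spatial connectome shared by read-only tests."""
    return make_spatial_connectome(SynthConfig(n_parcels=60, rng_seed=11))


@pytest.fixture(scope="session")
def medium_net() -> WeightedNetwork:
    """A 150-parcel spatial connectome shared by read-only tests."""
    return make_spatial_connectome(SynthConfig(n_parcels=150, rng_seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def path_graph(n: int = 3, weights=None) -> WeightedNetwork:
    """Chain 0-1-...-(n-1) with given consecutive weights (default all 1)."""
    w = np.zeros((n, n))
    weights = np.ones(n - 1) if weights is None else np.asarray(weights)
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = weights[i]
    return WeightedNetwork(w)
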