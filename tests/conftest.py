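import numpy as np
import pandas as pd
import pytest

from rbtsched.network import RoadNetwork
from rbtsched.synth import ScenarioSpec, make_network


@pytest.fixture(scope="session")
def grid_net():
    """Deterministic 6x6 grid (36 nodes, 60 links) around Melbourne coords."""
    return make_network(ScenarioSpec(n_nodes=36, seed=42))


@pytest.fixture(scope="session")
def small_net():
    """3x3 grid: 9 nodes, 12 links."""
    return make_network(ScenarioSpec(n_nodes=9, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def build_net(nodes, links, **kw):
    """Tiny helper: nodes {id: (lat, lon)}, links list of tuples
    (id, u, v, length_km, speed_kmh)."""
    df = pd.DataFrame(links, columns=["id", "u", "v", "length_km", "speed_kmh"])
    return RoadNetwork(nodes, df, **kw)
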