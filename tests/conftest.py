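import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hidpet.formats import GenomicInterval, IntervalSet
from hidpet.synth import FixtureConfig, simulate_network_truth, simulate_regulatory_landscape


@pytest.fixture
def two_triangles():
    """Two unit-weight triangles joined by one bridge edge."""
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]
    )
    return g


@pytest.fixture(scope="session")
def fixture_config():
    return FixtureConfig(seed=1)


@pytest.fixture(scope="session")
def landscape(fixture_config):
    return simulate_regulatory_landscape(fixture_config)


@pytest.fixture(scope="session")
def network_truth(fixture_config):
    return simulate_network_truth(fixture_config)


def make_intervals(name, triples):
    return IntervalSet(name, [GenomicInterval(c, s, e) for c, s, e in triples])


def random_graph(rng: np.random.Generator, n: int, p: float) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
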