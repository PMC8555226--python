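import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def toy_graph():
    """Triangle a-b-c with pendant d on c (hand-enumerable metrics)."""
    return nx.Graph([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])


@pytest.fixture
def path4():
    return nx.path_graph(["a", "b", "c", "d"])


def random_graph(rng, n_max=12):
    """Small Erdos-Renyi graph with random density, string node ids."""
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.1, 0.9)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes()})


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
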