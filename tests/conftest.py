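import networkx as nx
import numpy as np
import pytest

from seedprox import InteractionNetwork


def make_network(edges) -> InteractionNetwork:
    return InteractionNetwork(graph=nx.Graph(edges))


@pytest.fixture
def toy_network() -> InteractionNetwork:
    """5-node graph whose distance structure is checkable by hand.

    M-A, M-B, A-C, B-C, C-D: from M, {A, B} are at distance 1, C at 2, D at 3.
    """
    return make_network([("M", "A"), ("M", "B"), ("A", "C"), ("B", "C"), ("C", "D")])


@pytest.fixture
def myd88_network() -> InteractionNetwork:
    """Mini network around MYD88 with the interactor roles named in the text:
    NFKBIA a direct interactor, AKT2 two steps away via the kinase IRAK4."""
    return make_network(
        [
            ("MYD88", "NFKBIA"),
            ("MYD88", "IRAK4"),
            ("IRAK4", "AKT2"),
            ("MYD88", "TLR2"),
            ("TLR2", "SEPTIN9"),
        ]
    )


@pytest.fixture(scope="session")
def pa_network() -> InteractionNetwork:
    """Medium preferential-attachment network shared by the slower tests."""
    graph = nx.barabasi_albert_graph(300, 3, seed=7)
    graph = nx.relabel_nodes(graph, {i: f"P{i:04d}" for i in graph.nodes})
    return InteractionNetwork(graph=graph)


def random_network(rng: np.random.Generator, max_nodes: int = 40) -> InteractionNetwork:
    """Random G(n, p) graph with string labels for oracle cross-checks."""
    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.05, 0.4))
    graph = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
    return InteractionNetwork(graph=graph)
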