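import random

import networkx as nx
import pytest

from keyplayers import Graph, build_graph, example_network


@pytest.fixture(scope="session")
def example24() -> Graph:
    """The packaged 24-node example network."""
    return example_network()


@pytest.fixture
def path4() -> Graph:
    return build_graph([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def star5() -> Graph:
    return build_graph([("c", f"l{i}") for i in range(4)])


def random_graph(seed: int, n: int | None = None, p: float | None = None) -> Graph:
    """Small random graph with string labels, for property tests."""
    rng = random.Random(seed)
    if n is None:
        n = rng.randint(2, 12)
    if p is None:
        p = rng.uniform(0.1, 0.9)
    labels = [f"n{i}" for i in range(n)]
    edges = [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return build_graph(edges, isolated_nodes=labels)


def to_networkx(g: Graph) -> nx.Graph:
    gnx = nx.Graph()
    gnx.add_nodes_from(g.nodes)
    gnx.add_edges_from(g.edges)
    return gnx
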