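import networkx as nx
import numpy as np
import pandas as pd
import pytest

from immunetwork import CATEGORIES, ExpressionMatrix, GeneAnnotation


def graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


@pytest.fixture
def two_triangles():
    return graph([("a", "b"), ("b", "c"), ("a", "c"),
                  ("x", "y"), ("y", "z"), ("x", "z")])


@pytest.fixture
def path4():
    return nx.path_graph(4)


@pytest.fixture
def star3():
    """K_{1,3}: a hub with three leaves (degrees 3, 1, 1, 1)."""
    return nx.star_graph(3)


@pytest.fixture
def small_matrix():
    data = pd.DataFrame(
        [[10.0, 0.0, 5.0], [30.0, 5.0, 10.0], [60.0, 95.0, 985.0]],
        index=["gA", "gB", "gC"], columns=["s1", "s2", "s3"])
    return ExpressionMatrix(data)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(42)
    data = pd.DataFrame(rng.integers(0, 500, size=(4, 3)).astype(float),
                        index=[f"g{i}" for i in range(4)],
                        columns=[f"s{j}" for j in range(3)])
    return ExpressionMatrix(data)


@pytest.fixture
def round_robin_annotation():
    genes = [f"g{i}" for i in range(20)]
    return GeneAnnotation(
        {g: CATEGORIES[i % len(CATEGORIES)] for i, g in enumerate(genes)})


def random_small_graph(seed):
    """A seeded random graph with <= 8 nodes and at least one edge."""
    rng = np.random.default_rng(seed)
    while True:
        n = int(rng.integers(3, 9))
        p = float(rng.uniform(0.2, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if g.number_of_edges() >= 1:
            return g
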