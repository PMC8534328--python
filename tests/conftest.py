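import itertools

import networkx as nx
import pytest


def make_graph(edges):
    """Canonical graph from (u, v) or (u, v, weight) tuples."""
    g = nx.Graph()
    for e in edges:
        u, v = e[0], e[1]
        w = e[2] if len(e) > 2 else 1.0
        g.add_edge(u, v, weight=w)
    return g


def add_clique(g, nodes, weight=1.0):
    for u, v in itertools.combinations(nodes, 2):
        g.add_edge(u, v, weight=weight)
    return g


@pytest.fixture
def path3():
    """A - B - C."""
    return make_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def k4():
    return add_clique(nx.Graph(), ["A", "B", "C", "D"])


@pytest.fixture
def k4_pendant_triangle():
    """K4 {A,B,C,D} plus X attached to A, where X also belongs to triangle {X,Y,Z}.

    Seeding at A yields the initial cluster {A,B,C,D,X}; pruning X is the
    unique strictly GE-decreasing removal (2.918 -> 1.730 bits).
    """
    g = add_clique(nx.Graph(), ["A", "B", "C", "D"])
    g.add_edge("A", "X", weight=1.0)
    add_clique(g, ["X", "Y", "Z"])
    return g


@pytest.fixture
def shared_node_cliques():
    """Two K7s each attached to a hub S via three of their members.

    The hub's removal delta is exactly zero from either side, so the
    seed-growth procedure keeps it in both clusters: a genuine overlap.
    """
    g = nx.Graph()
    add_clique(g, [f"A{i}" for i in range(1, 8)])
    add_clique(g, [f"B{i}" for i in range(1, 8)])
    for x in ["A1", "A2", "A3", "B1", "B2", "B3"]:
        g.add_edge("S", x, weight=1.0)
    return g
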