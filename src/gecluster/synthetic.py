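"""Synthetic networks with planted ground truth.

Three generators cover the verification needs of an entropy-based module
detector:

* **clique unions** — disjoint cliques, the exactly-recoverable limit;
* **planted partitions** — dense blocks (probability ``p_in`` within, ``p_out``
  between) optionally sharing nodes between consecutive blocks, to exercise
  overlapping-cluster detection;
* **Erdős–Rényi G(n, m) nulls** — random graphs with a fixed number of nodes
  and edges, where a modularity-seeking method should find (almost) nothing
  but singletons.

All generators take an integer seed and are deterministic for a fixed seed;
reference modules are returned in the same named-node-set form the
evaluation module consumes.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

__all__ = ["make_clique_union", "make_planted_partition", "make_er_random"]


def _empty_canonical(nodes) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    return g


def _block_node_lists(sizes, overlap_nodes: int) -> list[list[str]]:
    """Sequential node labels with `overlap_nodes` shared between consecutive blocks."""
    blocks = []
    start = 0
    for s in sizes:
        blocks.append([f"N{i:05d}" for i in range(start, start + s)])
        start += s - overlap_nodes
    return blocks


def make_clique_union(sizes, rng_seed: int = 0) -> tuple[nx.Graph, dict[str, frozenset]]:
    """Disjoint cliques of the given sizes; references are the cliques.

    The graph is deterministic (the seed is accepted for interface symmetry
    only).  Every clique must have at least 2 nodes.
    """
    sizes = list(sizes)
    if not sizes or any(s < 2 for s in sizes):
        raise ValueError(f"every clique size must be >= 2, got {sizes}")
    blocks = _block_node_lists(sizes, overlap_nodes=0)
    g = _empty_canonical(v for b in blocks for v in b)
    for block in blocks:
        for i, u in enumerate(block):
            for v in block[i + 1 :]:
                g.add_edge(u, v, weight=1.0)
    refs = {f"M{i + 1}": frozenset(b) for i, b in enumerate(blocks)}
    return g, refs


def make_planted_partition(
    sizes,
    p_in: float,
    p_out: float,
    overlap_nodes: int = 0,
    rng_seed: int = 0,
) -> tuple[nx.Graph, dict[str, frozenset]]:
    """Planted-partition graph with optional node sharing between blocks.

    Node pairs sharing at least one block are connected with probability
    ``p_in``, all other pairs with ``p_out``; consecutive blocks share
    ``overlap_nodes`` members.  References are the planted blocks.  With
    ``p_in=1, p_out=0, overlap_nodes=0`` this is exactly the clique union.
    """
    sizes = list(sizes)
    if not sizes or any(s < 2 for s in sizes):
        raise ValueError(f"every block size must be >= 2, got {sizes}")
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ValueError(f"need 0 <= p_out <= p_in <= 1, got p_in={p_in}, p_out={p_out}")
    if overlap_nodes < 0 or (len(sizes) > 1 and overlap_nodes >= min(sizes)):
        raise ValueError(f"overlap_nodes must be in [0, min(sizes)-1], got {overlap_nodes}")
    rng = np.random.default_rng(rng_seed)
    blocks = _block_node_lists(sizes, overlap_nodes)
    membership: dict[str, set[int]] = {}
    for b, block in enumerate(blocks):
        for v in block:
            membership.setdefault(v, set()).add(b)
    nodes = sorted(membership)
    g = _empty_canonical(nodes)
    for i, u in enumerate(nodes):
        mu = membership[u]
        for v in nodes[i + 1 :]:
            p = p_in if mu & membership[v] else p_out
            if p >= 1.0 or (p > 0.0 and rng.random() < p):
                g.add_edge(u, v, weight=1.0)
    refs = {f"M{i + 1}": frozenset(b) for i, b in enumerate(blocks)}
    return g, refs


def make_er_random(n: int, m: int, rng_seed: int = 0) -> nx.Graph:
    """Uniform simple graph with exactly n nodes and m edges (G(n, m) model)."""
    if n < 0 or m < 0 or m > n * (n - 1) // 2:
        raise ValueError(f"infeasible edge count m={m} for n={n}")
    raw = nx.gnm_random_graph(n, m, seed=rng_seed)
    g = nx.Graph()
    g.add_nodes_from(f"N{i:05d}" for i in range(n))
    g.add_edges_from((f"N{u:05d}", f"N{v:05d}", {"weight": 1.0}) for u, v in raw.edges)
    return g
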