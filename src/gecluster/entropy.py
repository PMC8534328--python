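"""Node and graph entropy for partitions and seed-cluster splits.

Graph entropy (GE) measures the modularity of a division of a graph: each
node's entropy is the Shannon entropy (base 2, bits) of the distribution of
its edges across the parts, and GE is the sum over all nodes.  A perfectly
modular division — every node's edges confined to one part — has GE 0;
lower GE means higher modularity.

For seed-growth clustering the graph is split in two: the seed cluster C and
everything else.  A node v with m edges into C and k edges out of C has

    e(v) = -p_i log2 p_i - p_o log2 p_o,   p_i = m/(m+k), p_o = k/(m+k)

in the unweighted mode.  Two weighted variants use the inside/outside weight
sums W_i and W_o of v's incident edges:

* multiplied weights (GE-MW):  e(v) = -W_i p_i log2 p_i - W_o p_o log2 p_o
  (each term scaled by its weight mass; note this is not bounded by 1 bit);
* weighted ratios (GE-WR):     e(v) = H2(W_i / (W_i + W_o))
  (edge-count ratios replaced by weight ratios; collapses to the unweighted
  entropy whenever all weights are equal).

:class:`SeedClusterState` caches per-node inside/outside tallies so that the
GE change of adding or removing one node touches only that node's neighbors
(a node's own entropy does not depend on its own membership).
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "EntropyMode",
    "STRICT_DECREASE",
    "node_entropy_partition",
    "graph_entropy_partition",
    "node_entropy_binary",
    "cluster_entropy",
    "delta_entropy_move",
    "SeedClusterState",
]

#: A move "decreases GE" iff its delta is below this threshold; the margin
#: prevents oscillation on exact ties under floating-point noise.
STRICT_DECREASE = -1e-12

_LOG2 = math.log(2.0)


class EntropyMode(str, Enum):
    """Which node-entropy formula to use for seed-cluster splits."""

    UNWEIGHTED = "unweighted"
    GE_MW = "ge-mw"  # multiplied weights; experimental, not bounded by 1 bit
    GE_WR = "ge-wr"  # weighted ratios


def _h2(p: float) -> float:
    """Binary entropy in bits; H2(0) = H2(1) = 0."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    q = 1.0 - p
    return -(p * math.log(p) + q * math.log(q)) / _LOG2


def _binary_entropy(mode: EntropyMode, m: int, k: int, wi: float, wo: float) -> float:
    """Entropy of one node given inside/outside edge counts and weight sums."""
    d = m + k
    if d == 0:
        return 0.0
    if mode is EntropyMode.UNWEIGHTED:
        return _h2(m / d)
    if mode is EntropyMode.GE_WR:
        w = wi + wo
        if w <= 0.0:
            return 0.0
        return _h2(wi / w)
    # GE-MW: weight each term of the unweighted formula by its weight mass
    e = 0.0
    pi = m / d
    po = k / d
    if pi > 0.0:
        e -= wi * pi * math.log(pi) / _LOG2
    if po > 0.0:
        e -= wo * po * math.log(po) / _LOG2
    return e


# ---------------------------------------------------------------------------
# Partition entropy (k-way)
# ---------------------------------------------------------------------------

def validate_partition(graph: nx.Graph, partition: Sequence[Iterable]) -> list[set]:
    """Check that `partition` is a disjoint cover of the graph's nodes."""
    parts = [set(p) for p in partition]
    if not parts:
        raise ValueError("partition must contain at least one subgraph")
    seen: set = set()
    for p in parts:
        if seen & p:
            raise ValueError(f"partition subgraphs overlap on {sorted(seen & p)[:5]}")
        seen |= p
    nodes = set(graph.nodes)
    if seen != nodes:
        missing = nodes - seen
        extra = seen - nodes
        raise ValueError(f"partition does not cover the node set (missing={len(missing)}, extra={len(extra)})")
    return parts


def node_entropy_partition(graph: nx.Graph, v, partition: Sequence[Iterable]) -> float:
    """Entropy of node v over the distribution of its edges across subgraphs.

    Returns -sum_i p(x_i) log2 p(x_i) where p(x_i) is the fraction of v's
    edges ending in subgraph C_i.  Isolated nodes return 0 by convention.
    """
    if v not in graph:
        raise KeyError(f"node {v!r} not in graph")
    deg = graph.degree(v)
    if deg == 0:
        return 0.0
    parts = [set(p) for p in partition]
    e = 0.0
    neighbors = list(graph[v])
    for part in parts:
        c = sum(1 for u in neighbors if u in part)
        if c:
            p = c / deg
            e -= p * math.log(p) / _LOG2
    return e


def graph_entropy_partition(graph: nx.Graph, partition: Sequence[Iterable]) -> float:
    """Graph entropy of a k-way partition: the sum of all node entropies.

    The lowest value indicates the highest modularity; a partition with no
    cross-subgraph edges has entropy exactly 0.
    """
    parts = validate_partition(graph, partition)
    return sum(node_entropy_partition(graph, v, parts) for v in graph)


# ---------------------------------------------------------------------------
# Binary (seed cluster vs rest) entropy
# ---------------------------------------------------------------------------

def _binary_tallies(graph: nx.Graph, v, cluster: set) -> tuple[int, int, float, float]:
    m = k = 0
    wi = wo = 0.0
    for u, data in graph[v].items():
        w = data.get("weight", 1.0)
        if u in cluster:
            m += 1
            wi += w
        else:
            k += 1
            wo += w
    return m, k, wi, wo


def node_entropy_binary(graph: nx.Graph, v, cluster: Iterable, mode: EntropyMode = EntropyMode.UNWEIGHTED) -> float:
    """Entropy of node v for the binary split (cluster, rest) in `mode`.

    Note that v's own membership is irrelevant: only the sides of its
    incident edges' far endpoints matter.
    """
    if v not in graph:
        raise KeyError(f"node {v!r} not in graph")
    cl = cluster if isinstance(cluster, (set, frozenset)) else set(cluster)
    return _binary_entropy(EntropyMode(mode), *_binary_tallies(graph, v, cl))


class _NetView:
    """Plain dict-of-dicts adjacency with degree and strength, for fast access."""

    __slots__ = ("adj", "deg", "strength", "nodes")

    def __init__(self, graph: nx.Graph):
        self.adj: dict = {
            v: {u: data.get("weight", 1.0) for u, data in nbrs.items()}
            for v, nbrs in graph.adj.items()
        }
        self.deg = {v: len(nbrs) for v, nbrs in self.adj.items()}
        self.strength = {v: sum(nbrs.values()) for v, nbrs in self.adj.items()}
        self.nodes = list(self.adj)


class SeedClusterState:
    """Seed-cluster membership with cached node entropies and running GE.

    Tallies (m, k, W_i, W_o) are stored sparsely: a node that has never been
    adjacent to the cluster keeps its implicit default (0, deg, 0, strength)
    and entropy 0, so construction and moves cost time proportional to the
    cluster's neighborhood, not the graph.
    """

    __slots__ = ("_view", "mode", "_cluster", "_tally", "_entropy", "total_entropy")

    def __init__(self, graph: nx.Graph | _NetView, cluster: Iterable, mode: EntropyMode = EntropyMode.UNWEIGHTED):
        view = graph if isinstance(graph, _NetView) else _NetView(graph)
        cl = set(cluster)
        if not cl:
            raise ValueError("seed cluster must be non-empty")
        unknown = cl - view.adj.keys()
        if unknown:
            raise KeyError(f"cluster nodes not in graph: {sorted(unknown)[:5]}")
        self._view = view
        self.mode = EntropyMode(mode)
        self._cluster = cl
        # tally[v] = [m, k, Wi, Wo]; absent => [0, deg, 0, strength]
        self._tally: dict = {}
        self._entropy: dict = {}
        for c in cl:
            for u, w in view.adj[c].items():
                t = self._tally.get(u)
                if t is None:
                    t = self._tally[u] = [0, view.deg[u], 0.0, view.strength[u]]
                t[0] += 1
                t[1] -= 1
                t[2] += w
                t[3] -= w
        total = 0.0
        for u, t in self._tally.items():
            e = _binary_entropy(self.mode, t[0], t[1], t[2], t[3])
            self._entropy[u] = e
            total += e
        self.total_entropy = total

    # -- read-only views ----------------------------------------------------

    @property
    def cluster(self) -> frozenset:
        return frozenset(self._cluster)

    def __contains__(self, v) -> bool:
        return v in self._cluster

    def __len__(self) -> int:
        return len(self._cluster)

    def tallies(self, v) -> tuple[int, int, float, float]:
        """(m, k, W_i, W_o) for node v: inside/outside edge counts and weight sums."""
        t = self._tally.get(v)
        if t is None:
            if v not in self._view.adj:
                raise KeyError(f"node {v!r} not in graph")
            return 0, self._view.deg[v], 0.0, self._view.strength[v]
        return t[0], t[1], t[2], t[3]

    def entropy_of(self, v) -> float:
        e = self._entropy.get(v)
        if e is None:
            if v not in self._view.adj:
                raise KeyError(f"node {v!r} not in graph")
            return 0.0
        return e

    def node_entropies(self) -> dict:
        """Entropy of every graph node (dense; intended for small graphs)."""
        return {v: self._entropy.get(v, 0.0) for v in self._view.nodes}

    # -- moves --------------------------------------------------------------

    def _check_move(self, v, direction: str) -> int:
        if direction not in ("add", "remove"):
            raise ValueError(f"direction must be 'add' or 'remove', got {direction!r}")
        if v not in self._view.adj:
            raise KeyError(f"node {v!r} not in graph")
        inside = v in self._cluster
        if direction == "add" and inside:
            raise ValueError(f"cannot add {v!r}: already in cluster")
        if direction == "remove" and not inside:
            raise ValueError(f"cannot remove {v!r}: not in cluster")
        return 1 if direction == "add" else -1

    def delta(self, v, direction: str) -> float:
        """GE change of moving v across the boundary, without mutating state.

        Only v's neighbors are touched: each neighbor u sees the edge (u, v)
        flip sides, shifting its tallies by one edge and weight w(u, v).
        v's own entropy is unchanged because it does not depend on v's
        membership.
        """
        sign = self._check_move(v, direction)
        mode = self.mode
        d = 0.0
        for u, w in self._view.adj[v].items():
            m, k, wi, wo = self.tallies(u)
            d += (
                _binary_entropy(mode, m + sign, k - sign, wi + sign * w, wo - sign * w)
                - self._entropy.get(u, 0.0)
            )
        return d

    def apply(self, v, direction: str) -> float:
        """Apply the move, updating tallies, entropies and the GE total.

        Returns the applied delta.
        """
        sign = self._check_move(v, direction)
        mode = self.mode
        view = self._view
        d = 0.0
        for u, w in view.adj[v].items():
            t = self._tally.get(u)
            if t is None:
                t = self._tally[u] = [0, view.deg[u], 0.0, view.strength[u]]
            t[0] += sign
            t[1] -= sign
            t[2] += sign * w
            t[3] -= sign * w
            e_new = _binary_entropy(mode, t[0], t[1], t[2], t[3])
            d += e_new - self._entropy.get(u, 0.0)
            self._entropy[u] = e_new
        if sign == 1:
            self._cluster.add(v)
        else:
            self._cluster.remove(v)
        self.total_entropy += d
        return d


def cluster_entropy(graph: nx.Graph, cluster: Iterable, mode: EntropyMode = EntropyMode.UNWEIGHTED) -> SeedClusterState:
    """Full recomputation of the GE of a binary (cluster, rest) split.

    Returns a :class:`SeedClusterState` whose ``total_entropy`` is the graph
    entropy; only nodes incident to the cluster can carry nonzero entropy.
    """
    return SeedClusterState(graph, cluster, mode)


def delta_entropy_move(state: SeedClusterState, v, direction: str) -> float:
    """GE change of adding/removing v, computed incrementally (pure query)."""
    return state.delta(v, direction)
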