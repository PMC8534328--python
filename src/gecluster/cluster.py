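"""Seed-growth clustering by local graph-entropy minimization.

One cluster is grown per seed, in six steps:

1. among nodes not yet covered by an earlier cluster, pick the one with the
   highest degree (lexicographic tie-break) as the seed;
2. initialize the seed cluster as the seed plus all its neighbors;
3. prune: visit the seed's neighbors once, in descending degree order, and
   remove each one whose removal strictly decreases GE (the seed stays);
4. grow: repeatedly sweep the cluster's outside neighbors in descending
   degree order, adding each one whose addition strictly decreases GE,
   until a full sweep adds nothing (pruned nodes may be re-added);
5. emit the cluster in its minimized state;
6. mark all members covered and repeat until every node is covered.

Because each cluster is grown independently and only the *seed* must be
uncovered, clusters may overlap.  Singleton clusters are dropped from the
output (but still count as covered, which guarantees termination).  The
procedure is fully deterministic: there is no randomness and every ordering
is fixed by (degree, node identifier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from gecluster.entropy import (
    STRICT_DECREASE,
    EntropyMode,
    SeedClusterState,
    _NetView,
)

__all__ = [
    "ClusterRecord",
    "ClusterSet",
    "select_seed",
    "init_seed_cluster",
    "prune_phase",
    "growth_phase",
    "run_ge",
    "write_clusters_tsv",
    "write_clusters_gmt",
]


@dataclass(frozen=True)
class ClusterRecord:
    """One emitted cluster: its members, seed of origin and final GE."""

    members: frozenset
    seed: str
    final_ge: float
    mode: EntropyMode

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Ordered, possibly overlapping clusters plus the covered-node set.

    ``covered`` includes members of singleton clusters that were excluded
    from ``clusters``, so it can be a superset of the union of members.
    """

    clusters: list[ClusterRecord] = field(default_factory=list)
    covered: set = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def memberships(self) -> dict[str, frozenset]:
        """cluster id -> members, ids assigned in emission order (C1, C2, ...)."""
        return {f"C{i + 1}": rec.members for i, rec in enumerate(self.clusters)}

    @property
    def average_size(self) -> float:
        if not self.clusters:
            return 0.0
        return sum(len(c) for c in self.clusters) / len(self.clusters)


def _degree_order_key(view: _NetView):
    deg = view.deg
    return lambda v: (-deg[v], v)


def select_seed(graph: nx.Graph, covered: Iterable) -> Optional[str]:
    """Highest-degree node outside `covered`, lexicographic tie-break; None if exhausted."""
    cov = set(covered)
    best = None
    for v in graph.nodes:
        if v in cov:
            continue
        key = (-graph.degree(v), v)
        if best is None or key < best[0]:
            best = (key, v)
    return None if best is None else best[1]


def init_seed_cluster(graph: nx.Graph, seed) -> set:
    """The seed node together with all its neighbors."""
    if seed not in graph:
        raise KeyError(f"seed {seed!r} not in graph")
    return {seed} | set(graph[seed])


def prune_phase(graph: nx.Graph, state: SeedClusterState, seed) -> SeedClusterState:
    """Remove seed neighbors whose removal strictly decreases GE.

    Each of the seed's original neighbors is visited exactly once, in
    descending degree order; the seed itself is never removed.  Mutates and
    returns `state`.
    """
    view = state._view
    order = sorted((u for u in view.adj[seed] if u in state), key=_degree_order_key(view))
    for u in order:
        if state.delta(u, "remove") < STRICT_DECREASE:
            state.apply(u, "remove")
    return state


def growth_phase(graph: nx.Graph, state: SeedClusterState) -> SeedClusterState:
    """Add outside neighbors of the cluster while GE strictly decreases.

    Sweeps re-collect the cluster's neighbor set, visit it in descending
    degree order and add every node whose delta is strictly negative; the
    phase ends when a full sweep adds nothing.  Nodes removed by the prune
    phase are eligible again.  Mutates and returns `state`.
    """
    view = state._view
    key = _degree_order_key(view)
    for _ in range(len(view.nodes)):  # each sweep adds >= 1 node or stops
        frontier = set()
        for c in state.cluster:
            for u in view.adj[c]:
                if u not in state:
                    frontier.add(u)
        added = False
        for u in sorted(frontier, key=key):
            if u in state:  # pragma: no cover - frontier is outside by construction
                continue
            if state.delta(u, "add") < STRICT_DECREASE:
                state.apply(u, "add")
                added = True
        if not added:
            break
    return state


def run_ge(
    graph: nx.Graph,
    mode: EntropyMode = EntropyMode.UNWEIGHTED,
    min_cluster_size: int = 2,
) -> ClusterSet:
    """Run the full seed-growth procedure over the graph.

    Parameters
    ----------
    graph
        Canonical undirected graph; weights are read from the ``weight``
        edge attribute (ignored in UNWEIGHTED mode).
    mode
        Entropy formula for the weighted variants.
    min_cluster_size
        Clusters smaller than this are excluded from the output (default 2:
        singletons are dropped).  Their members still count as covered.

    Returns
    -------
    ClusterSet
        Clusters in emission order.  Deterministic for a fixed input.
    """
    mode = EntropyMode(mode)
    result = ClusterSet()
    if graph.number_of_nodes() == 0:
        return result
    view = _NetView(graph)
    # Seeds are drawn from a fixed (degree desc, name) order; a pointer walk
    # suffices because coverage only grows.
    seed_order = sorted(view.nodes, key=_degree_order_key(view))
    pos = 0
    covered = result.covered
    while True:
        while pos < len(seed_order) and seed_order[pos] in covered:
            pos += 1
        if pos == len(seed_order):
            break
        seed = seed_order[pos]
        members = {seed} | set(view.adj[seed])
        state = SeedClusterState(view, members, mode)
        prune_phase(graph, state, seed)
        growth_phase(graph, state)
        final = state.cluster
        covered.update(final)
        if len(final) >= min_cluster_size:
            result.clusters.append(
                ClusterRecord(members=final, seed=seed, final_ge=state.total_entropy, mode=mode)
            )
    return result


def write_clusters_tsv(clusters: ClusterSet, path) -> None:
    """One cluster per line: id, seed, final GE, size, then sorted members."""
    with open(path, "w") as fh:
        for i, rec in enumerate(clusters, start=1):
            members = "\t".join(sorted(rec.members))
            fh.write(f"C{i}\t{rec.seed}\t{rec.final_ge:.6f}\t{len(rec)}\t{members}\n")


def write_clusters_gmt(clusters: ClusterSet, path) -> None:
    """GMT-compatible writer: id, 'GE' description column, then members."""
    with open(path, "w") as fh:
        for i, rec in enumerate(clusters, start=1):
            members = "\t".join(sorted(rec.members))
            fh.write(f"C{i}\tGE\t{members}\n")
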