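"""Scoring cluster sets against reference module sets.

References (protein complexes, GO term annotation groups) are named node
sets.  Each cluster is matched to its best-scoring reference:

    P_ij = |C_i ∩ r_j| / |C_i|        (precision)
    R_ij = |C_i ∩ r_j| / |r_j|        (recall)
    F_ij = 2 P_ij R_ij / (P_ij + R_ij)

The average F-score and average precision take the per-cluster maximum over
references and average over clusters.  Before scoring, reference members
absent from the network are removed from the references, and cluster members
absent from the (filtered) reference universe are removed from the clusters;
sets emptied by the filtering are dropped entirely.

Also provided: the proportion of functionally homogeneous clusters (best
precision >= 0.6), overlap statistics (nodes appearing in >= 2 clusters and
clusters containing such nodes), and novel-member proposal: clusters whose
best F-score against *unfiltered* references exceeds 0.9 nominate their
members missing from that reference as candidate new annotations.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from gecluster.cluster import ClusterSet

__all__ = [
    "read_gmt",
    "write_gmt",
    "pair_scores",
    "filter_for_evaluation",
    "best_matches",
    "average_fscore",
    "average_precision",
    "homogeneity_proportion",
    "overlap_statistics",
    "propose_novel_members",
    "evaluate",
    "EvaluationReport",
    "write_report",
]

Clusters = Mapping[str, frozenset]
References = Mapping[str, frozenset]


def _as_cluster_map(clusters) -> dict[str, frozenset]:
    """Accept a ClusterSet, mapping, or sequence of sets; return id -> frozenset."""
    if isinstance(clusters, ClusterSet):
        return clusters.memberships()
    if isinstance(clusters, Mapping):
        return {str(k): frozenset(v) for k, v in clusters.items()}
    return {f"C{i + 1}": frozenset(c) for i, c in enumerate(clusters)}


def read_gmt(path: str | os.PathLike) -> dict[str, frozenset]:
    """Read GMT gene-set lines (name, description, members...) into name -> set.

    Member identifiers are upper-cased to match canonical graph nodes.
    Duplicate set names raise; empty member lists are dropped.
    """
    refs: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: GMT needs at least name and description")
            name = fields[0]
            if name in refs:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = frozenset(f.upper() for f in fields[2:] if f.strip())
            if members:
                refs[name] = members
    return refs


def write_gmt(refs: References, path: str | os.PathLike, description: str = "NA") -> None:
    with open(path, "w") as fh:
        for name in sorted(refs):
            fh.write(name + "\t" + description + "\t" + "\t".join(sorted(refs[name])) + "\n")


def pair_scores(cluster: Iterable, reference: Iterable) -> tuple[float, float, float]:
    """(precision, recall, F-score) of one cluster against one reference.

    F is 0 when the sets are disjoint (P + R = 0).
    """
    c = frozenset(cluster)
    r = frozenset(reference)
    if not c or not r:
        raise ValueError("cluster and reference must both be non-empty")
    inter = len(c & r)
    p = inter / len(c)
    rec = inter / len(r)
    f = 2.0 * p * rec / (p + rec) if p + rec > 0 else 0.0
    return p, rec, f


def filter_for_evaluation(
    clusters, graph: nx.Graph, refs: References
) -> tuple[dict[str, frozenset], dict[str, frozenset]]:
    """Apply the reciprocal exclusion rules before scoring.

    Reference members not present in the network are dropped from each
    reference; cluster members not present in the filtered reference
    universe are dropped from each cluster.  References or clusters that
    become empty are removed entirely (they cannot be scored).
    """
    nodes = set(graph.nodes)
    frefs = {}
    for name, members in refs.items():
        kept = frozenset(members) & nodes
        if kept:
            frefs[name] = frozenset(kept)
    universe = set().union(*frefs.values()) if frefs else set()
    fclusters = {}
    for cid, members in _as_cluster_map(clusters).items():
        kept = members & universe
        if kept:
            fclusters[cid] = frozenset(kept)
    return fclusters, frefs


def best_matches(clusters, refs: References, metric: str = "f") -> list[tuple[str, str, float]]:
    """Per cluster, the best (reference, score) under 'f' or 'p'.

    Ties between references are broken by reference name so reports are
    deterministic; the scores themselves are tie-independent.
    """
    if metric not in ("f", "p"):
        raise ValueError("metric must be 'f' or 'p'")
    cmap = _as_cluster_map(clusters)
    out = []
    ref_items = sorted(refs.items())
    for cid, members in cmap.items():
        best_name, best_score = "", 0.0
        for name, rmembers in ref_items:
            p, _, f = pair_scores(members, rmembers)
            score = f if metric == "f" else p
            if score > best_score:
                best_name, best_score = name, score
        out.append((cid, best_name, best_score))
    return out


def _mean_best(clusters, refs, metric: str) -> float:
    matches = best_matches(clusters, refs, metric)
    if not matches:
        raise ValueError("no scorable clusters (did filtering empty the set?)")
    if not refs:
        raise ValueError("no references to score against")
    return sum(s for _, _, s in matches) / len(matches)


def average_fscore(clusters, refs: References) -> float:
    """Mean over clusters of the best F-score against any reference."""
    return _mean_best(clusters, refs, "f")


def average_precision(clusters, refs: References) -> float:
    """Mean over clusters of the best precision against any reference."""
    return _mean_best(clusters, refs, "p")


def homogeneity_proportion(clusters, refs: References, threshold: float = 0.6) -> float:
    """Percent of clusters whose best precision is >= threshold (inclusive)."""
    matches = best_matches(clusters, refs, "p")
    if not matches:
        raise ValueError("no scorable clusters")
    hits = sum(1 for _, _, s in matches if s >= threshold)
    return 100.0 * hits / len(matches)


def overlap_statistics(clusters) -> tuple[frozenset, int, float]:
    """(overlapping nodes, count of overlapping clusters, percent of clusters).

    A node appearing in two or more clusters is overlapping; a cluster
    containing at least one overlapping node is an overlapping cluster.
    Membership is counted once per cluster.  Invariant to cluster order.
    """
    cmap = _as_cluster_map(clusters)
    if not cmap:
        return frozenset(), 0, 0.0
    count: dict = {}
    for members in cmap.values():
        for v in members:
            count[v] = count.get(v, 0) + 1
    overlapping = frozenset(v for v, c in count.items() if c >= 2)
    n_clusters = sum(1 for members in cmap.values() if members & overlapping)
    return overlapping, n_clusters, 100.0 * n_clusters / len(cmap)


def propose_novel_members(
    clusters, refs_unfiltered: References, f_threshold: float = 0.9
) -> list[tuple[str, str, frozenset, float]]:
    """Clusters matching an unfiltered reference with F strictly above threshold.

    The references must *not* have been filtered against the network: a
    cluster member absent from the matched reference is precisely the novel
    candidate being proposed.  Returns (cluster id, reference, novel
    members, F) for qualifying clusters with a non-trivial best match.
    """
    out = []
    ref_items = sorted(refs_unfiltered.items())
    for cid, members in _as_cluster_map(clusters).items():
        best_name, best_f = "", 0.0
        for name, rmembers in ref_items:
            _, _, f = pair_scores(members, rmembers)
            if f > best_f:
                best_name, best_f = name, f
        if best_f > f_threshold:
            novel = members - refs_unfiltered[best_name]
            if novel:
                out.append((cid, best_name, frozenset(novel), best_f))
    return out


@dataclass
class EvaluationReport:
    """Aggregate accuracy of a cluster set against one reference collection."""

    per_cluster: list[tuple[str, str, float]]  # (cluster id, best reference, best F)
    mean_f: float
    mean_p: float
    n_evaluated: int
    homogeneity_pct: float
    overlapping_nodes: frozenset
    n_overlapping_clusters: int
    overlap_pct: float
    novel_members: list[tuple[str, str, frozenset, float]] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "mean_f": self.mean_f,
            "mean_p": self.mean_p,
            "homogeneity_pct": self.homogeneity_pct,
            "n_overlapping_nodes": len(self.overlapping_nodes),
            "n_overlapping_clusters": self.n_overlapping_clusters,
            "overlap_pct": self.overlap_pct,
            "n_novel_proposals": len(self.novel_members),
        }


def evaluate(
    clusters,
    graph: nx.Graph,
    refs: References,
    homogeneity_threshold: float = 0.6,
    novel_f_threshold: float | None = None,
) -> EvaluationReport:
    """Full evaluation pipeline: filter, score, aggregate.

    Overlap statistics are computed on the raw (unfiltered) cluster set,
    since overlap is a property of the clustering itself, not of the
    reference.  Novel members, if requested, are scored against the raw
    references by design.
    """
    fclusters, frefs = filter_for_evaluation(clusters, graph, refs)
    if not fclusters or not frefs:
        raise ValueError("nothing to evaluate after filtering")
    per_cluster = best_matches(fclusters, frefs, "f")
    mean_f = sum(s for _, _, s in per_cluster) / len(per_cluster)
    mean_p = average_precision(fclusters, frefs)
    homog = homogeneity_proportion(fclusters, frefs, homogeneity_threshold)
    onodes, oclusters, opct = overlap_statistics(clusters)
    novel = (
        propose_novel_members(clusters, refs, novel_f_threshold)
        if novel_f_threshold is not None
        else []
    )
    return EvaluationReport(
        per_cluster=per_cluster,
        mean_f=mean_f,
        mean_p=mean_p,
        n_evaluated=len(per_cluster),
        homogeneity_pct=homog,
        overlapping_nodes=onodes,
        n_overlapping_clusters=oclusters,
        overlap_pct=opct,
        novel_members=novel,
    )


def write_report(report: EvaluationReport, prefix: str | os.PathLike) -> None:
    """Write <prefix>.percluster.tsv and a machine-readable <prefix>.summary.json."""
    with open(f"{prefix}.percluster.tsv", "w") as fh:
        fh.write("cluster_id\tbest_reference\tbest_f\n")
        for cid, ref, score in report.per_cluster:
            fh.write(f"{cid}\t{ref}\t{score:.6f}\n")
    with open(f"{prefix}.summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
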