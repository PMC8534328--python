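"""Reading, canonicalizing and weighting undirected PPI networks.

Graphs are plain :class:`networkx.Graph` objects in canonical form:

* node identifiers are upper-cased strings (gene symbols are conventionally
  capitalized);
* no self-loops, no duplicate undirected edges (duplicates collapse to the
  maximum weight, keeping the strongest evidence);
* every edge carries a finite ``weight >= 0`` (1.0 for unweighted input);
* edges read from the STRING physical-links dialect additionally carry an
  integer ``score`` attribute (the raw combined score, 0-999) so that
  probabilistic weights can be derived later.
"""

from __future__ import annotations

import math
import os
from typing import Iterable

import networkx as nx

__all__ = [
    "read_edge_list",
    "read_string_links",
    "write_edge_list",
    "apply_probabilistic_weights",
    "apply_topological_weights",
    "validate_graph",
]


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list or STRING-links file."""


def _add_canonical_edge(g: nx.Graph, u: str, v: str, weight: float, score: int | None = None) -> None:
    u, v = u.upper(), v.upper()
    if u == v:
        return
    if g.has_edge(u, v):
        # redundant link: keep the strongest evidence
        if weight > g[u][v]["weight"]:
            g[u][v]["weight"] = weight
        if score is not None and score > g[u][v].get("score", -1):
            g[u][v]["score"] = score
    else:
        if score is None:
            g.add_edge(u, v, weight=weight)
        else:
            g.add_edge(u, v, weight=weight, score=score)


def read_edge_list(
    path: str | os.PathLike,
    has_weights: bool = False,
    delimiter: str | None = None,
) -> nx.Graph:
    """Read a 2- or 3-column edge list into a canonical graph.

    Parameters
    ----------
    path
        Text file with one edge per line: ``node node [weight]``.  Lines
        starting with ``#`` and blank lines are ignored.
    has_weights
        If True, a third column with a non-negative weight is required;
        otherwise every edge gets weight 1.0 (a third column, if present,
        is ignored).
    delimiter
        Field separator; ``None`` splits on any whitespace (tabs or spaces).

    Returns
    -------
    networkx.Graph
        Canonical graph: upper-cased nodes, self-loops dropped, duplicate
        undirected edges collapsed to the maximum weight.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise EdgeListParseError(f"{path}: line {lineno}: expected at least 2 fields, got {len(fields)}")
            if has_weights:
                if len(fields) < 3:
                    raise EdgeListParseError(f"{path}: line {lineno}: expected a weight in column 3")
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise EdgeListParseError(f"{path}: line {lineno}: bad weight {fields[2]!r}") from exc
                if not math.isfinite(w) or w < 0:
                    raise EdgeListParseError(f"{path}: line {lineno}: weight must be finite and >= 0, got {w}")
            else:
                w = 1.0
            _add_canonical_edge(g, fields[0], fields[1], w)
    return g


def read_string_links(path: str | os.PathLike, score_threshold: int = 700) -> nx.Graph:
    """Read a STRING physical-links file, keeping high-confidence edges.

    The file has a header row and columns ``protein1 protein2 combined_score``
    with an integer score in 0-999.  Only edges with
    ``score >= score_threshold`` are retained (the conventional
    high-confidence cut-off is 700, inclusive).  The raw score is kept as an
    edge attribute for later conversion to a probabilistic weight.
    """
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise EdgeListParseError(f"{path}: empty file, expected a header row")
        ncols = len(header.split())
        if ncols < 3:
            raise EdgeListParseError(f"{path}: header has {ncols} columns, expected protein1 protein2 combined_score")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise EdgeListParseError(f"{path}: line {lineno}: expected 3 fields, got {len(fields)}")
            try:
                score = int(fields[2])
            except ValueError as exc:
                raise EdgeListParseError(f"{path}: line {lineno}: non-integer combined_score {fields[2]!r}") from exc
            if score < score_threshold:
                continue
            _add_canonical_edge(g, fields[0], fields[1], 1.0, score=score)
    return g


def write_edge_list(graph: nx.Graph, path: str | os.PathLike) -> None:
    """Write a canonical 3-column TSV edge list, sorted for diff stability."""
    lines = []
    for u, v, w in graph.edges(data="weight", default=1.0):
        a, b = sorted((u, v))
        lines.append((a, b, w))
    lines.sort()
    with open(path, "w") as fh:
        for a, b, w in lines:
            fh.write(f"{a}\t{b}\t{w!r}\n")


def apply_probabilistic_weights(graph: nx.Graph) -> nx.Graph:
    """Set each edge weight to its STRING confidence score / 1000.

    STRING combined scores are integers in 0-999 interpreted as
    probabilities scaled by 1000, so a score of 900 becomes weight 0.9.
    Returns a new graph; the input is not modified.
    """
    out = graph.copy()
    for u, v, data in out.edges(data=True):
        if "score" not in data:
            raise ValueError(f"edge ({u}, {v}) has no retained confidence score")
        data["weight"] = data["score"] / 1000.0
    return out


def apply_topological_weights(graph: nx.Graph) -> nx.Graph:
    """Weight each edge by the Jaccard index of its endpoints' neighborhoods.

    For an edge {u, v} the weight is |N(u) ∩ N(v)| / |N(u) ∪ N(v)| where the
    neighbor sets exclude u and v themselves, so the weight is a pure
    common-neighbor ratio.  Edges whose endpoints have no other neighbors get
    weight 0.  Returns a new graph; the input is not modified.
    """
    out = graph.copy()
    adj = {v: set(out[v]) for v in out}
    for u, v, data in out.edges(data=True):
        nu = adj[u] - {u, v}
        nv = adj[v] - {u, v}
        union = nu | nv
        data["weight"] = len(nu & nv) / len(union) if union else 0.0
    return out


def validate_graph(graph: nx.Graph) -> None:
    """Raise ValueError if the graph violates the canonical-form invariants."""
    for v in graph:
        if not isinstance(v, str) or v != v.upper():
            raise ValueError(f"node {v!r} is not an upper-cased string")
    for u, v, w in graph.edges(data="weight", default=None):
        if u == v:
            raise ValueError(f"self-loop on {u}")
        if w is None or not math.isfinite(w) or w < 0:
            raise ValueError(f"edge ({u}, {v}) has invalid weight {w!r}")
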