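"""Weighted undirected graphs: representation, invariants, components, file I/O.

A graph is a symmetric n x n weight matrix with zero diagonal and weights in
[0, 1]; an edge exists iff its weight is strictly positive.  Node identifiers
are consecutive 0-based integers.  Isolated nodes are legal everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc


class GraphDomainError(ValueError):
    """An input violates a graph invariant (weight range, symmetry, ids...)."""


class GraphParseError(ValueError):
    """A graph file is malformed; the message names the offending line."""


_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric non-negative weight matrix over ``n`` nodes.

    Parameters
    ----------
    weights
        ``(n, n)`` float array; symmetric, zero diagonal, entries in [0, 1].
        Weight 0 means "no edge"; there is no separate missing-value code.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise GraphDomainError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] < 1:
            raise GraphDomainError("graph must have at least one node")
        if not np.allclose(w, w.T, rtol=0.0, atol=_SYMMETRY_TOL):
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise GraphDomainError(
                f"weight matrix is asymmetric at ({i},{j}): {w[i, j]} != {w[j, i]}"
            )
        if np.any(np.diag(w) != 0.0):
            i = int(np.flatnonzero(np.diag(w))[0])
            raise GraphDomainError(f"nonzero self-loop weight at node {i}")
        if np.any(w < 0.0) or np.any(w > 1.0):
            i, j = np.unravel_index(int(np.argmax((w < 0) | (w > 1))), w.shape)
            raise GraphDomainError(
                f"edge weight out of [0, 1] at ({i},{j}): {w[i, j]}"
            )
        # exact symmetry after validation keeps downstream linear algebra clean
        w = (w + w.T) / 2.0
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def node_ids(self) -> np.ndarray:
        return np.arange(self.n)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights)))

    def edges(self) -> list[tuple[int, int, float]]:
        """Edges as ``(i, j, w)`` with ``i < j``, lexicographic order."""
        iu, ju = np.nonzero(np.triu(self.weights))
        return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(iu, ju)]

    def degree(self) -> np.ndarray:
        """Per-node count of incident positive-weight edges."""
        return (self.weights > 0).sum(axis=1)

    def to_igraph(self):
        """Export to a python-igraph Graph with a ``weight`` edge attribute."""
        import igraph as ig

        es = self.edges()
        g = ig.Graph(
            n=self.n,
            edges=[(i, j) for i, j, _ in es],
            edge_attrs={"weight": [w for _, _, w in es]},
        )
        return g

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_weighted_edges_from(self.edges())
        return g


@dataclass(frozen=True)
class ComponentLabeling:
    """Connected-component labels: nodes share a label iff a positive-weight
    path joins them."""

    labels: np.ndarray
    n_components: int


def connected_components(graph: WeightedGraph) -> ComponentLabeling:
    """Label maximal mutually reachable node sets; isolated nodes are singletons."""
    n_comp, labels = _cc(sp.csr_matrix(graph.weights), directed=False)
    return ComponentLabeling(labels=labels, n_components=int(n_comp))


@dataclass(frozen=True)
class NodeRemoval:
    """Result of :func:`remove_nodes`: the surviving graph plus the relabeling.

    ``old_to_new[i]`` is the new consecutive id of old node ``i``, or -1 if
    removed.
    """

    graph: WeightedGraph
    old_to_new: np.ndarray = field(repr=False)


def remove_nodes(graph: WeightedGraph, nodes) -> NodeRemoval:
    """Delete a node set and every incident edge; survivors are relabeled
    consecutively (0..n'-1 in ascending old-id order)."""
    nodes = np.asarray(sorted(set(int(v) for v in nodes)), dtype=int)
    if nodes.size and (nodes.min() < 0 or nodes.max() >= graph.n):
        raise GraphDomainError(
            f"unknown node id in removal set (n={graph.n}): {nodes.tolist()}"
        )
    keep = np.setdiff1d(np.arange(graph.n), nodes)
    if keep.size == 0:
        raise GraphDomainError("cannot remove all nodes: graphs need n >= 1")
    old_to_new = np.full(graph.n, -1, dtype=int)
    old_to_new[keep] = np.arange(keep.size)
    sub = graph.weights[np.ix_(keep, keep)]
    return NodeRemoval(graph=WeightedGraph(sub), old_to_new=old_to_new)


def remove_edges(graph: WeightedGraph, edges) -> WeightedGraph:
    """Zero out the listed edges; the node count is unchanged."""
    w = graph.weights.copy()
    for i, j in edges:
        i, j = int(i), int(j)
        if not (0 <= i < graph.n and 0 <= j < graph.n) or w[i, j] == 0.0:
            raise GraphDomainError(f"edge ({i},{j}) does not exist")
        w[i, j] = 0.0
        w[j, i] = 0.0
    return WeightedGraph(w)


# ---------------------------------------------------------------------------
# File formats.
#
# edgelist_tsv: header "# n=<int>", then "<i>\t<j>\t<w>" rows with i < j.
# matrix_csv:   n rows of n comma-separated decimals, no header.
# ---------------------------------------------------------------------------

FORMATS = ("edgelist_tsv", "matrix_csv")


def read_graph(path, format: str = "edgelist_tsv") -> WeightedGraph:
    """Read a weighted graph from ``path`` in the named dialect.

    Matrix input must already be symmetric (to 1e-9); asymmetry is an error,
    never silently averaged away.
    """
    if format == "edgelist_tsv":
        return _read_edgelist(path)
    if format == "matrix_csv":
        return _read_matrix(path)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def write_graph(graph: WeightedGraph, path, format: str = "edgelist_tsv") -> None:
    """Write ``graph`` to ``path``; round-trips weights to 1e-12."""
    if format == "edgelist_tsv":
        lines = [f"# n={graph.n}"]
        lines += [f"{i}\t{j}\t{w:.17g}" for i, j, w in graph.edges()]
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "matrix_csv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for row in graph.weights:
                fh.write(",".join(f"{x:.17g}" for x in row) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def _read_edgelist(path) -> WeightedGraph:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("# n="):
        raise GraphParseError(f"{path}: line 1: expected header '# n=<int>'")
    try:
        n = int(lines[0][4:])
    except ValueError as exc:
        raise GraphParseError(f"{path}: line 1: bad node count {lines[0]!r}") from exc
    if n < 1:
        raise GraphDomainError(f"{path}: node count must be >= 1, got {n}")
    w = np.zeros((n, n))
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GraphParseError(f"{path}: line {ln}: expected 3 tab-separated fields")
        try:
            i, j, wt = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as exc:
            raise GraphParseError(f"{path}: line {ln}: unparseable row {line!r}") from exc
        if not (0 <= i < n and 0 <= j < n):
            raise GraphDomainError(f"{path}: line {ln}: node id out of range 0..{n - 1}")
        if i == j:
            raise GraphDomainError(f"{path}: line {ln}: self-loop on node {i}")
        if not (0.0 < wt <= 1.0):
            raise GraphDomainError(f"{path}: line {ln}: weight {wt} outside (0, 1]")
        w[i, j] = wt
        w[j, i] = wt
    return WeightedGraph(w)


def _read_matrix(path) -> WeightedGraph:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append([float(x) for x in line.strip().split(",")])
            except ValueError as exc:
                raise GraphParseError(f"{path}: line {ln}: unparseable row") from exc
    if not rows:
        raise GraphParseError(f"{path}: empty matrix file")
    n = len(rows)
    if any(len(r) != n for r in rows):
        bad = next(ln for ln, r in enumerate(rows, start=1) if len(r) != n)
        raise GraphParseError(f"{path}: line {bad}: expected {n} columns")
    return WeightedGraph(np.array(rows))
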