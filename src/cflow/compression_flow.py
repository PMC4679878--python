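"""Compression Flow (CF): summed compression ratios of periphery-to-core walks.

The statistic treats functional integration as lossy data compression: ``t``
units of information are injected at ``t`` randomly chosen peripheral (low
betweenness) nodes and allowed to drift toward the network core along random
walks that climb the edge-centrality gradient.  The union of all traversed
edges forms a provisional graph; the more the walks converge onto shared
routes, the fewer nodes the union merges, and the higher the compression
ratio rho_t = t / (number of node merges).  CF is the sum of rho_t over input
loads t = 1..k, where k is the periphery size.

Walk rule: from the current node the walker may only take incident edges whose
driving value (edge betweenness by default, raw weight optionally) is strictly
greater than that of the edge it arrived by, choosing among candidates with
probability proportional to the driving value.  The strict increase forbids
re-taking the inward edge, prevents loops, and guarantees termination; a walk
ends when no admissible edge remains, i.e. when it has reached a local
centrality summit — the network core.
"""

from __future__ import annotations

import random
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from cflow.graph_core import ComponentLabeling, GraphDomainError, WeightedGraph
from cflow.netstats import betweenness, edge_betweenness

WALK_DRIVES = ("edge_betweenness", "edge_weight")
FORMULA_VARIANTS = ("rank", "components")

#: relative resolution below which two centrality values are considered equal.
#: Betweenness on symmetric graphs (e.g. ring lattices) is exactly tied in
#: real arithmetic but accumulates last-ulp float noise; snapping keeps the
#: percentile pivot and the strict-increase walk rule faithful to the exact
#: tie structure.
CENTRALITY_RESOLUTION = 1e-12


def _snap(values: np.ndarray) -> np.ndarray:
    """Round to 12 significant digits relative to the maximum magnitude."""
    values = np.asarray(values, dtype=float)
    scale = np.max(np.abs(values)) if values.size else 0.0
    if scale == 0.0:
        return values
    return np.round(values / scale, 12) * scale


@dataclass(frozen=True)
class CFParameters:
    """Tunable parameters of a CF run.

    theta_percentile
        Percentile of the node-betweenness distribution that defines the
        periphery pivot; low values (5-10) select only the most peripheral
        nodes and the choice in that range barely moves CF.
    walk_drive
        Edge attribute that steers the walks: ``edge_betweenness`` (default;
        walks climb toward globally loaded edges) or ``edge_weight``.
    formula_variant
        ``rank`` (default): rho_t = t / (n - |c(G_hat)|), i.e. load over the
        number of node merges performed by the walked-edge union.
        ``components``: rho_t = t / |c(G_hat)| for sensitivity analysis.
    reps_per_load
        Independent repetitions averaged per load t.
    """

    theta_percentile: float = 5.0
    walk_drive: str = "edge_betweenness"
    formula_variant: str = "rank"
    reps_per_load: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_percentile < 50.0):
            raise ValueError(
                f"theta_percentile must lie in (0, 50), got {self.theta_percentile}"
            )
        if self.walk_drive not in WALK_DRIVES:
            raise ValueError(f"walk_drive must be one of {WALK_DRIVES}")
        if self.formula_variant not in FORMULA_VARIANTS:
            raise ValueError(f"formula_variant must be one of {FORMULA_VARIANTS}")
        if self.reps_per_load < 1:
            raise ValueError("reps_per_load must be >= 1")


@dataclass(frozen=True)
class WalkRecord:
    """One random walk: visited nodes, traversed edges, and why it stopped."""

    start: int
    node_seq: tuple
    edge_seq: tuple
    termination: str  # "no_admissible_edge" | "isolated_start"


@dataclass(frozen=True)
class CompressionResult:
    """Per-load compression ratios and their sum CF."""

    periphery: np.ndarray
    rho: np.ndarray
    cf: float
    params: CFParameters
    walks: Optional[list] = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return int(self.periphery.size)

    def to_dict(self) -> dict:
        return {
            "cf": self.cf,
            "k": self.k,
            "rho": self.rho.tolist(),
            "params": {
                "theta_percentile": self.params.theta_percentile,
                "walk_drive": self.params.walk_drive,
                "formula_variant": self.params.formula_variant,
                "reps_per_load": self.params.reps_per_load,
                "seed": self.params.seed,
            },
        }


def peripheral_nodes(
    graph: WeightedGraph, node_bc: np.ndarray, theta_percentile: float = 5.0
) -> np.ndarray:
    """Nodes whose betweenness does not exceed the pivot percentile value.

    The pivot theta is the ``theta_percentile``-th percentile of the BC
    distribution (linear interpolation); membership uses BC <= theta so a
    degenerate all-equal distribution yields the whole node set rather than
    an empty periphery.
    """
    node_bc = np.asarray(node_bc, dtype=float)
    if graph.n < 3:
        raise GraphDomainError(f"periphery needs n >= 3, got n={graph.n}")
    if node_bc.shape != (graph.n,):
        raise GraphDomainError("node_bc length must equal the node count")
    node_bc = _snap(node_bc)
    theta = np.percentile(node_bc, theta_percentile)
    phi = np.flatnonzero(node_bc <= theta)
    if phi.size == 0:  # unreachable with <=, kept as a belt-and-braces guard
        phi = np.array([int(np.argmin(node_bc))])
    return phi


class _WalkEngine:
    """Per-node incident edges sorted by driving value, with cumulative sums
    for O(log deg) proportional sampling over the admissible suffix."""

    def __init__(self, graph: WeightedGraph, drive: dict):
        n = graph.n
        self.nbrs: list[list[int]] = [[] for _ in range(n)]
        self.drv: list[list[float]] = [[] for _ in range(n)]
        self.cum: list[list[float]] = [[] for _ in range(n)]
        per_node: list[list[tuple[float, int]]] = [[] for _ in range(n)]
        for (i, j), d in drive.items():
            per_node[i].append((float(d), j))
            per_node[j].append((float(d), i))
        for u in range(n):
            per_node[u].sort()
            tot = 0.0
            for d, v in per_node[u]:
                self.nbrs[u].append(v)
                self.drv[u].append(d)
                tot += d
                self.cum[u].append(tot)

    def walk(self, start: int, rng: random.Random):
        """Yield the traversed edges as (u, v) pairs; nodes in visit order."""
        nodes = [start]
        edges = []
        u = start
        d_in = 0.0
        while True:
            drv = self.drv[u]
            lo = bisect_right(drv, d_in)
            if lo >= len(drv):
                break
            cum = self.cum[u]
            base = cum[lo - 1] if lo else 0.0
            total = cum[-1] - base
            if total <= 0.0:
                break
            pick = bisect_right(cum, base + rng.random() * total, lo)
            if pick >= len(drv):  # guard against float round-off at the top
                pick = len(drv) - 1
            v = self.nbrs[u][pick]
            d_in = drv[pick]
            edges.append((u, v))
            nodes.append(v)
            u = v
        return nodes, edges


def _edge_drive(graph: WeightedGraph, walk_drive: str) -> dict:
    if walk_drive == "edge_weight":
        drive = {(i, j): w for i, j, w in graph.edges()}
    else:
        drive = edge_betweenness(graph)
    keys = list(drive)
    snapped = _snap(np.array([drive[k] for k in keys]))
    return {k: float(v) for k, v in zip(keys, snapped)}


def single_walk(
    graph: WeightedGraph, drive: dict, start: int, rng: random.Random
) -> WalkRecord:
    """Run one centrality-climbing walk from ``start``.

    ``drive`` maps each edge ``(i, j)`` with ``i < j`` to its driving value.
    An isolated start yields an empty walk.
    """
    if not (0 <= start < graph.n):
        raise GraphDomainError(f"start node {start} out of range 0..{graph.n - 1}")
    engine = _WalkEngine(graph, drive)
    if graph.degree()[start] == 0:
        return WalkRecord(start, (start,), (), "isolated_start")
    nodes, edges = engine.walk(start, rng)
    return WalkRecord(start, tuple(nodes), tuple(edges), "no_admissible_edge")


class _UnionFind:
    __slots__ = ("parent", "merges")

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}
        self.merges = 0

    def find(self, x: int) -> int:
        p = self.parent
        root = p.setdefault(x, x)
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
            self.merges += 1


def provisional_graph(walks: Sequence, n: int) -> tuple[ComponentLabeling, int]:
    """Component structure of the provisional graph G_hat: all ``n`` nodes
    plus the union of every edge encountered in the walks.

    Returns the labeling and the merge count n - |c(G_hat)| (the rank of the
    walked edge union; duplicated edges collapse).
    """
    uf = _UnionFind()
    for w in walks:
        edge_seq = w.edge_seq if isinstance(w, WalkRecord) else w
        for a, b in edge_seq:
            if not (0 <= a < n and 0 <= b < n):
                raise GraphDomainError(f"walked edge ({a},{b}) outside 0..{n - 1}")
            uf.union(a, b)
    labels = np.arange(n)
    for x in uf.parent:
        labels[x] = uf.find(x)
    # compact labels
    _, labels = np.unique(labels, return_inverse=True)
    n_comp = n - uf.merges
    return ComponentLabeling(labels=labels, n_components=n_comp), uf.merges


def compression_flow(
    graph: WeightedGraph,
    params: CFParameters = CFParameters(),
    keep_walks: bool = False,
) -> CompressionResult:
    """Estimate the Compression Flow of a weighted graph.

    For each input load t = 1..k, t distinct start nodes are drawn uniformly
    without replacement from the periphery, one walk is launched per start,
    and rho_t is computed from the component structure of the walked-edge
    union (averaged over ``reps_per_load`` repetitions).  CF = sum_t rho_t.
    Fully reproducible under a fixed seed.
    """
    if graph.n < 3:
        raise GraphDomainError(f"CF needs n >= 3, got n={graph.n}")
    if graph.n_edges == 0:
        raise GraphDomainError("CF undefined on an edgeless graph")
    bc = betweenness(graph)
    phi = peripheral_nodes(graph, bc, params.theta_percentile)
    drive = _edge_drive(graph, params.walk_drive)
    engine = _WalkEngine(graph, drive)
    rng = random.Random(params.seed)
    n = graph.n
    k = phi.size
    phi_list = [int(v) for v in phi]
    rho = np.zeros(k)
    kept: Optional[list] = [] if keep_walks else None
    for t in range(1, k + 1):
        acc = 0.0
        for _ in range(params.reps_per_load):
            starts = rng.sample(phi_list, t)
            uf = _UnionFind()
            load_walks = [] if keep_walks else None
            for s in starts:
                nodes, edges = engine.walk(s, rng)
                for a, b in edges:
                    uf.union(a, b)
                if keep_walks:
                    term = (
                        "no_admissible_edge"
                        if graph.degree()[s] > 0
                        else "isolated_start"
                    )
                    load_walks.append(WalkRecord(s, tuple(nodes), tuple(edges), term))
            merges = uf.merges
            if params.formula_variant == "rank":
                acc += t / merges if merges >= 1 else 0.0
            else:
                acc += t / (n - merges)
            if keep_walks:
                kept.append(load_walks)
        rho[t - 1] = acc / params.reps_per_load
    return CompressionResult(
        periphery=phi, rho=rho, cf=float(rho.sum()), params=params, walks=kept
    )


def cf_of_model_suite(
    graphs: Sequence[WeightedGraph], params: CFParameters = CFParameters()
) -> np.ndarray:
    """CF for each graph in order, with per-graph seeds derived as
    ``params.seed + index`` so batch entries are decoupled."""
    return np.array(
        [
            compression_flow(g, replace(params, seed=params.seed + i)).cf
            for i, g in enumerate(graphs)
        ]
    )
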