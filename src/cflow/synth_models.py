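"""Synthetic network families and the random-removal degradation experiment.

Four generator families cover the validation setting: two brain-like
topologies — Watts-Strogatz small-world (WS) and Barabasi-Albert
core-periphery (BA) — and two null models — Erdos-Renyi random (ER) and the
deterministic ring lattice (RL).  The degradation experiment removes a growing
fraction of nodes (or edges) uniformly at random from freshly generated
graphs, emulating diffuse neurodegeneration, and tracks how each network
statistic decays across Monte-Carlo runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from cflow.compression_flow import CFParameters, compression_flow
from cflow.graph_core import GraphDomainError, WeightedGraph, remove_edges, remove_nodes
from cflow.netstats import (
    best_partition,
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    edge_betweenness,
    modularity,
    node_strength,
)

FAMILIES = ("WS", "BA", "ER", "RL")
WEIGHT_MODES = ("unit", "uniform01")
METRICS = ("CF", "L", "C", "Q", "strength", "BC", "EBC")


@dataclass(frozen=True)
class ModelSpec:
    """Parameters of one synthetic network family.

    Defaults follow the validation setting: n = 2**10 nodes and a matched
    mean degree of 20 across families so cross-family CF comparisons are
    density-controlled; WS rewiring probability 0.1 sits in the canonical
    small-world regime.  ``weight_mode='unit'`` gives binary-weight graphs;
    ``'uniform01'`` draws i.i.d. Uniform(0, 1] weights to exercise the
    weighted code paths.
    """

    family: str = "WS"
    n: int = 1024
    mean_degree: int = 20
    rewire_p: float = 0.1
    seed: int = 0
    weight_mode: str = "unit"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise GraphDomainError(f"family must be one of {FAMILIES}")
        if self.n < 4:
            raise GraphDomainError(f"n must be >= 4, got {self.n}")
        if self.family in ("WS", "RL") and self.mean_degree % 2:
            raise GraphDomainError(
                f"{self.family} needs an even mean degree, got {self.mean_degree}"
            )
        if not (0.0 <= self.rewire_p <= 1.0):
            raise GraphDomainError(f"rewire_p must be in [0, 1], got {self.rewire_p}")
        if self.weight_mode not in WEIGHT_MODES:
            raise GraphDomainError(f"weight_mode must be one of {WEIGHT_MODES}")


@dataclass(frozen=True)
class DegradationCurve:
    """Metric values across removal fractions and Monte-Carlo runs."""

    fractions: np.ndarray
    metric_name: str
    values: np.ndarray  # runs x fractions
    removal_mode: str
    n_runs: int

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


def generate(spec: ModelSpec) -> WeightedGraph:
    """Generate one seeded graph of the requested family.

    WS: ring lattice with mean_degree neighbors, each edge rewired with
    probability rewire_p.  BA: preferential attachment adding
    mean_degree/2 edges per arriving node.  ER: G(n, p) with
    p = mean_degree/(n-1).  RL: the deterministic ring lattice (WS at
    rewire_p = 0).
    """
    rng_seed = int(spec.seed)
    if spec.family == "WS":
        g = nx.watts_strogatz_graph(spec.n, spec.mean_degree, spec.rewire_p, seed=rng_seed)
    elif spec.family == "RL":
        g = nx.watts_strogatz_graph(spec.n, spec.mean_degree, 0.0, seed=rng_seed)
    elif spec.family == "BA":
        m = max(1, spec.mean_degree // 2)
        g = nx.barabasi_albert_graph(spec.n, m, seed=rng_seed)
    else:  # ER
        p = spec.mean_degree / (spec.n - 1)
        g = nx.fast_gnp_random_graph(spec.n, p, seed=rng_seed)
    w = np.zeros((spec.n, spec.n))
    edges = np.array(g.edges(), dtype=int)
    if edges.size:
        if spec.weight_mode == "unit":
            vals = np.ones(edges.shape[0])
        else:
            rng = np.random.default_rng(rng_seed)
            # Uniform(0, 1]: avoid a zero weight, which would delete the edge
            vals = 1.0 - rng.random(edges.shape[0])
        w[edges[:, 0], edges[:, 1]] = vals
        w[edges[:, 1], edges[:, 0]] = vals
    return WeightedGraph(w)


def degrade(
    graph: WeightedGraph, fraction: float, mode: str = "node", seed: int = 0
) -> WeightedGraph:
    """Remove round(fraction * n) uniformly chosen nodes, or
    round(fraction * |E|) uniformly chosen edges."""
    if not (0.0 <= fraction < 1.0):
        raise GraphDomainError(f"removal fraction must be in [0, 1), got {fraction}")
    if mode not in ("node", "edge"):
        raise GraphDomainError(f"mode must be 'node' or 'edge', got {mode!r}")
    if fraction == 0.0:
        return graph
    rng = np.random.default_rng(seed)
    if mode == "node":
        n_remove = int(round(fraction * graph.n))
        if n_remove == 0:
            return graph
        victims = rng.choice(graph.n, size=n_remove, replace=False)
        return remove_nodes(graph, victims).graph
    edges = graph.edges()
    n_remove = int(round(fraction * len(edges)))
    if n_remove == 0:
        return graph
    idx = rng.choice(len(edges), size=n_remove, replace=False)
    return remove_edges(graph, [(edges[i][0], edges[i][1]) for i in idx])


def _evaluate_metric(
    graph: WeightedGraph, metric: str, cf_params: CFParameters, seed: int
) -> float:
    if metric == "CF":
        return compression_flow(graph, replace(cf_params, seed=seed)).cf
    if metric == "L":
        return characteristic_path_length(graph)
    if metric == "C":
        return clustering_coefficient(graph)[1]
    if metric == "Q":
        part = best_partition(graph, gamma=1.15, seed=seed)
        return modularity(graph, part)
    if metric == "strength":
        return float(node_strength(graph).mean())
    if metric == "BC":
        return float(betweenness(graph).mean())
    if metric == "EBC":
        ebc = edge_betweenness(graph)
        return float(np.mean(list(ebc.values()))) if ebc else 0.0
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def run_degradation_experiment(
    spec: ModelSpec,
    fractions: Sequence[float],
    n_runs: int = 100,
    metrics: Sequence[str] = ("CF", "L"),
    removal_mode: str = "node",
    cf_params: Optional[CFParameters] = None,
    seed: int = 0,
) -> dict[str, DegradationCurve]:
    """Monte-Carlo degradation curves for one network family.

    Per run: a fresh graph (seed = master seed + run index), then per removal
    fraction an independent seeded degradation and metric evaluation.  The
    run count defaults to 100, a scaled-down version of the 1000-run
    averaging in the original validation; pass ``n_runs=1000`` to restore it.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    fractions = np.asarray(sorted(fractions), dtype=float)
    if fractions.size == 0 or fractions[0] != 0.0:
        raise ValueError("fractions must start at 0 (the intact baseline)")
    if np.unique(fractions).size != fractions.size:
        raise ValueError("fractions must be strictly increasing")
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}; expected a subset of {METRICS}")
    cf_params = cf_params if cf_params is not None else CFParameters()
    values = {m: np.zeros((n_runs, fractions.size)) for m in metrics}
    for run in range(n_runs):
        run_seed = seed + run
        g0 = generate(replace(spec, seed=run_seed))
        for fi, frac in enumerate(fractions):
            g = degrade(g0, float(frac), mode=removal_mode, seed=run_seed * 1000 + fi)
            for m in metrics:
                values[m][run, fi] = _evaluate_metric(g, m, cf_params, seed=run_seed)
    return {
        m: DegradationCurve(
            fractions=fractions,
            metric_name=m,
            values=values[m],
            removal_mode=removal_mode,
            n_runs=n_runs,
        )
        for m in metrics
    }


def percent_change(curve: DegradationCurve, at_fraction: float) -> float:
    """Percentage loss of the metric mean at ``at_fraction`` relative to the
    intact (fraction-0) mean: 100 * (mean_0 - mean_f) / mean_0."""
    fr = curve.fractions
    match = np.flatnonzero(np.isclose(fr, at_fraction))
    if match.size == 0:
        raise ValueError(f"fraction {at_fraction} not in curve grid {fr.tolist()}")
    baseline = curve.values[:, 0].mean()
    if baseline == 0.0:
        raise ZeroDivisionError("percent change undefined: zero baseline mean")
    return float(100.0 * (baseline - curve.values[:, match[0]].mean()) / baseline)
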