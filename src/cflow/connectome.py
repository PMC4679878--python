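"""Significance-filtered Pearson-correlation connectomes from time series.

A recording is an m x n matrix (timepoints x nodes).  For every node pair the
Pearson correlation r and its two-sided p-value (t transform, m-2 degrees of
freedom) are computed; an edge is kept with weight r when p < alpha and
r > 0, so the connectome is a weighted graph with weights in (0, 1].
Negative correlations are dropped by default, keeping the adjacency matrix in
[0, 1]; ``use_abs=True`` retains |r| instead for sensitivity analysis.

The synthetic generator emulates the blockwise-correlated structure of
preprocessed resting-state signals: nodes in the same block share a latent
factor whose variance is set so the expected pairwise within-block
correlation equals ``within_r``; the default session length is 140
timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from cflow.compression_flow import CFParameters, CompressionResult, compression_flow
from cflow.graph_core import WeightedGraph
from cflow.netstats import NetStatsSummary, summarize


class SeriesError(ValueError):
    """A time-series matrix violates a precondition (shape, constant column)."""


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """m x n signal block: rows are timepoints, columns are nodes/voxels."""

    data: np.ndarray
    node_labels: Optional[tuple] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise SeriesError(f"series must be 2-D (timepoints x nodes), got {d.ndim}-D")
        if d.shape[0] < 3:
            raise SeriesError(
                f"need at least 3 timepoints for a correlation p-value, got {d.shape[0]}"
            )
        sd = d.std(axis=0)
        if np.any(sd == 0.0):
            col = int(np.flatnonzero(sd == 0.0)[0])
            raise SeriesError(f"column {col} is constant (zero variance)")
        if self.node_labels is not None and len(self.node_labels) != d.shape[1]:
            raise SeriesError("node_labels length must equal the node count")
        object.__setattr__(self, "data", d)
        if d.shape[0] < 10:
            warnings.warn(
                f"only {d.shape[0]} timepoints: correlation p-values are unstable",
                stacklevel=2,
            )

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_csv(cls, path, max_timepoints: Optional[int] = None) -> "TimeSeriesMatrix":
        """Read an m x n CSV, optionally with a header row of node labels.

        ``max_timepoints`` truncates longer recordings to a nominal session
        length (e.g. 140 frames).
        """
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        labels = None
        skip = 0
        try:
            [float(x) for x in first.strip().split(",")]
        except ValueError:
            labels = tuple(x.strip() for x in first.strip().split(","))
            skip = 1
        data = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
        if max_timepoints is not None:
            data = data[:max_timepoints]
        return cls(data=data, node_labels=labels)


@dataclass(frozen=True)
class SynthSeriesSpec:
    """Planted-block synthetic signal specification.

    Each of ``n_blocks`` blocks shares a latent Gaussian factor; node signals
    are factor + N(0, noise_sd^2) noise, with the factor variance chosen so
    the expected within-block pairwise correlation is ``within_r``
    (closed form r = v / (v + sigma^2), hence v = r sigma^2 / (1 - r)).
    """

    n_nodes: int = 200
    m_timepoints: int = 140
    n_blocks: int = 4
    within_r: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.within_r < 1.0):
            raise SeriesError(f"within_r must lie in (0, 1), got {self.within_r}")
        if self.n_blocks > self.n_nodes:
            raise SeriesError("n_blocks cannot exceed n_nodes")
        if self.n_blocks < 1 or self.n_nodes < 2 or self.m_timepoints < 3:
            raise SeriesError("need n_blocks >= 1, n_nodes >= 2, m_timepoints >= 3")
        if self.noise_sd <= 0.0:
            raise SeriesError("noise_sd must be positive")


def pearson_connectome(
    series: TimeSeriesMatrix, alpha: float = 0.05, use_abs: bool = False
) -> WeightedGraph:
    """Weighted graph of significant positive Pearson correlations.

    Edge weight = r where the two-sided p-value (t transform with m-2 df) is
    below ``alpha`` and r > 0; everything else is 0.  With ``use_abs`` the
    sign rule is dropped and |r| is kept instead.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    m = series.m
    r = np.corrcoef(series.data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    with np.errstate(divide="ignore", over="ignore"):
        tstat = r * np.sqrt((m - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=m - 2)
    w = np.abs(r) if use_abs else np.where(r > 0.0, r, 0.0)
    w = np.where(p < alpha, w, 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w)


def generate_series(spec: SynthSeriesSpec) -> TimeSeriesMatrix:
    """Draw one seeded block-structured time-series matrix."""
    rng = np.random.default_rng(spec.seed)
    sigma2 = spec.noise_sd**2
    v = spec.within_r * sigma2 / (1.0 - spec.within_r)
    factors = rng.normal(0.0, np.sqrt(v), size=(spec.m_timepoints, spec.n_blocks))
    block_of = np.arange(spec.n_nodes) % spec.n_blocks
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.m_timepoints, spec.n_nodes))
    data = factors[:, block_of] + noise
    return TimeSeriesMatrix(data=data)


def series_to_summary(
    series: TimeSeriesMatrix,
    alpha: float = 0.05,
    gamma: float = 1.15,
    cf_params: Optional[CFParameters] = None,
) -> tuple[NetStatsSummary, CompressionResult]:
    """End-to-end subject record: correlation graph -> statistics panel + CF."""
    cf_params = cf_params if cf_params is not None else CFParameters()
    graph = pearson_connectome(series, alpha=alpha)
    summary = summarize(graph, gamma=gamma, seed=cf_params.seed)
    cf = compression_flow(graph, cf_params)
    return summary, cf
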