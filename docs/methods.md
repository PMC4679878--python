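# Methods

## Model and conventions

`cflow` works on weighted undirected graphs with weights in [0, 1], zero
diagonal, and "weight 0 = no edge". All shortest-path quantities (pairwise
distances d_ij, characteristic path length L, node betweenness BC, edge
betweenness EBC) use the inverse-weight edge length 1/a_ij, so a strong
functional connection is a short hop. BC is normalized over the
(n−1)(n−2) ordered endpoint pairs; EBC over the n(n−1) ordered pairs.
Unreachable pairs are excluded from the L average (rather than imputed), and
the finite-pair fraction is reported alongside L so disconnection is never
silent. The weighted clustering coefficient is the geometric-mean triangle
intensity C_i = 2t_i/(k_i(k_i−1)), t_i = ½ Σ (a_ij a_ih a_jh)^{1/3}, taken
on the raw weights — deliberately *without* the max-weight rescaling some
libraries apply, so an all-0.5 triangle scores C = 0.5, not 1. Modularity
uses l = the grand sum of the weight matrix (each undirected edge counted
twice), with the resolution γ multiplying the null term; community detection
is greedy multilevel (Louvain) at γ = 1.15 by default, which counteracts the
optimizer's preference for oversized modules on dense correlation graphs and
is seeded for reproducibility.

Betweenness is delegated to igraph's Brandes implementation and renormalized
to the conventions above; equal-length path multiplicity is shared
fractionally. On disconnected graphs eigenvector centrality is computed on
the largest component (others score 0), via power iteration on W + I — the
shift leaves the Perron vector unchanged but guarantees convergence on
bipartite blocks, where the unshifted spectrum has |λ_min| = λ_max.

## Compression Flow

CF estimates integration capacity as the summed compression ratios of
periphery-to-core random walks (see README for the algorithm). Design
choices that were genuinely open:

* **Walk drive.** Walks are driven by edge betweenness by default: EBC is
  what orients "periphery → core", and it remains informative on
  binary-weight graphs, where raw weights carry no gradient and every
  weight-driven walk would stop after one step. Raw-weight driving is
  available (`walk_drive="edge_weight"`).
* **Strict increase.** A candidate edge must have a driving value strictly
  greater than the inward edge's. This single rule subsumes
  "exclude the inward edge" (its value is equal, not greater), prevents
  cycles without any visited-set bookkeeping, and bounds every walk by the
  number of distinct driving values. Revisiting nodes is permitted.
* **Tie snapping.** Driving values and node BC are snapped to 12 significant
  digits before comparisons. On symmetric graphs (ring lattices) betweenness
  is exactly tied in real arithmetic, but C-level implementations return
  values differing in the last ulp; without snapping those phantom
  differences would arbitrarily split an all-equal periphery. With snapping,
  an all-equal BC distribution yields φ = V, as it should.
* **Periphery membership** uses BC ≤ ϑ (not <) so a degenerate BC
  distribution still yields a nonempty periphery; ϑ is the linear-interpolated
  percentile (default 5).
* **ρ_t denominator.** Ĝ is defined over all n nodes, so n − |c(Ĝ)| is the
  number of merges performed by the walked-edge union (the rank of that edge
  set). When no edge is walked, ρ_t = 0 (nothing was condensed). The
  alternative reading ρ_t = t/|c(Ĝ)| is available as
  `formula_variant="components"` for sensitivity analysis.
* **Loads.** Start nodes are drawn without replacement, one walk per start,
  `reps_per_load` (default 1) repetitions averaged per load. Batch
  evaluation derives per-graph seeds as `seed + index`.

**Scaling caveat.** CF ≈ ρ̄·k where k = |φ| and ρ̄ is the mean per-load
compression ratio. Because k is pinned by the pivot percentile, CF itself
scales with the pivot (moving ϑ from the 5th to the 10th percentile roughly
doubles CF), while the normalized ρ̄ = CF/k is what is insensitive to the
pivot (measured shift 0.5% on 50 seeded small-world graphs). Comparisons
across graphs of different sizes should keep the percentile fixed, and
tie-induced changes in k (see below) dominate CF under degradation.

## Synthetic families and the degradation experiment

Four generator families at matched size and density: Watts–Strogatz
(small-world; rewiring p = 0.1, the canonical small-world regime),
Barabási–Albert (core–periphery; m = mean_degree/2 edges per arrival),
Erdős–Rényi and the deterministic ring lattice as null models. Defaults:
n = 2¹⁰ nodes, mean degree 20, unit weights (an `uniform01` mode exercises
the weighted code paths). The degradation experiment removes
round(fraction·n) nodes (or round(fraction·|E|) edges) uniformly at random —
node mode is the default protocol — and evaluates any subset of
{CF, L, C, Q, strength, BC, EBC} per run and fraction. The run count
defaults to 100 (the full design uses 1000; pass `n_runs=1000` to restore
it), with per-run seeds derived from the master seed. The acceptance script
and the acceptance tests use n = 1024, mean degree 20, 100 runs.

**What the validation does and does not show.** Under these conditions CF
declines sharply and significantly under node removal in all families, and
L's blindness to WS/BA degradation does *not* reproduce: L shifts are small
(e.g. 2.56 → 2.84 on BA at 50% removal) but the Monte-Carlo variance is
tiny, so rank tests flag them. Two further headline effects depend on
betweenness *ties*, not topology per se: (i) cross-family CF differences are
small at matched density (BA vs WS ≈ −7%), because the percentile pivot pins
k to ~5% of n in every family — large CF excesses require a family whose BC
distribution has heavy ties at the bottom (e.g. preferential attachment with
m = 1–2, where zero-BC leaves make φ the whole leaf set), which matched
density rules out; (ii) the intact ring lattice has an all-equal BC
distribution, so φ = V and CF ≈ 10³, and removing 6.5% of nodes collapses φ
back to ~5% of n — a ~99% CF loss, the extreme form of lattice fragility. A
sensitivity sweep over rewire_p ∈ {0.05, 0.1, 0.2} and
mean_degree ∈ {10, 20, 30}, and over both walk drives and weight modes, does
not change picture (i): the BA-vs-WS gap stays within ±10%. Conclusions
drawn from this validation therefore concern tie structure and periphery
size as much as walk convergence, and transfer to real connectomes — whose
BC distributions are continuous but heavy-tailed — only qualitatively.

## Connectomes from time series

`pearson_connectome` computes all pairwise Pearson correlations of an
m × n time-series matrix with two-sided p-values from the t transform
(m − 2 df), and keeps weight r where p < α (default 0.05) *and* r > 0 —
negative correlations are dropped to keep weights in [0, 1]
(`use_abs=True` keeps |r| instead). No multiple-testing correction is
applied by default; under the null the retained-edge rate is α/2 (half of
the two-sided false positives are negative), which the calibration test
checks at m = 140, n = 200. P-values are one test per edge; with fewer than
10 timepoints the module warns that they are unstable. CSV input may carry a
header row of node labels and can be truncated to a nominal session length
(`max_timepoints`, e.g. 140 frames).

The synthetic generator plants blockwise correlation: nodes in a block share
a latent Gaussian factor with variance v = r·σ²/(1−r), giving expected
within-block pairwise correlation r against N(0, σ²) noise. It emulates the
second-order structure the connectome stage assumes — m ≈ 140 timepoints,
blockwise-correlated stationary signals — and none of the things real
recordings have (autocorrelation, drift, motion artifacts, spatial weight
structure), so passing tests validate the pipeline's statistics, not its
robustness to physiological confounds.

## Statistical layer

Rank-sum comparisons use the exact permutation distribution when the
combined sample is ≤ 20 and tie-free, and the tie-corrected normal
approximation otherwise. Kruskal–Wallis uses the tie-corrected H with a
χ²(groups−1) p-value. The Mann–Kendall trend test is implemented directly
(S statistic, tie-corrected variance, continuity correction). Bonferroni
correction in the pairwise class report multiplies by the number of class
pairs and caps at 1. Reported p-values keep full precision; a display
column rounds to three decimals, so "0.000" means p < 0.0005.

## Numerical and degenerate-input policy

Asymmetric matrix input is an error (tolerance 1e-9), never silently
symmetrized. Isolated nodes are legal everywhere; the panel's `n_nodes`
counts non-isolated nodes. Edgeless graphs are rejected by CF, eigenvector
centrality, Louvain and L (undefined), and zero-variance time-series columns
are rejected at construction naming the column. File round-trips preserve
weights to 1e-12 (17 significant digits written). Power iteration runs to
relative tolerance 1e-10.

## Limitations

* CF is a Monte-Carlo estimate; per-graph variance at default
  `reps_per_load=1` is substantial on small graphs (use `reps_per_load` or
  averaging over seeds for stable per-subject scores).
* The percentile periphery makes CF discontinuous in the presence of BC
  ties; ranked comparisons across graphs with very different tie structure
  (e.g. lattices vs random graphs) mix two effects (see above).
* Weighted BC on near-tied shortest paths depends on floating-point length
  comparisons; the 12-digit snapping addresses exact symmetric ties only.
* The connectome stage assumes stationarity and exchangeable timepoints; it
  performs no preprocessing (detrending, nuisance regression, realignment).
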