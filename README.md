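# cflow

Compression Flow (CF) and weighted complex-network statistics for functional
connectomes.

## The problem

Functional integration — the capacity of a networked system (canonically the
brain) to bind information from specialized regions into a coherent whole —
is classically proxied by the characteristic path length *L*. But *L* is
insensitive to some forms of structural degradation: hub-dominated
(core–periphery) networks can lose half their nodes with almost no change in
*L*. `cflow` implements **Compression Flow**, a random-walk statistic that
treats integration as lossy data compression, along with everything needed to
study it: the standard weighted network-statistics panel, synthetic network
families with a random-removal degradation experiment, a
significance-filtered Pearson-correlation connectome builder for time-series
data, and a nonparametric comparison layer.

## The statistic

Given a weighted undirected graph *G* with *n* nodes (weights in [0, 1],
edge length 1/weight for all shortest-path quantities):

1. Compute node betweenness BC and edge betweenness EBC. Set the pivot ϑ at a
   low percentile (default 5) of the BC distribution; the periphery
   φ = {v : BC_v ≤ ϑ} with k = |φ|.
2. For each input load t = 1..k, activate t distinct peripheral nodes chosen
   uniformly at random. From each, launch a random walk that at every step
   picks an incident edge whose driving value (EBC by default) is **strictly
   greater** than that of the edge it arrived by, with probability
   proportional to the driving value. Each walk halts at a local centrality
   summit — the network core.
3. Form the provisional graph Ĝ on all n nodes from the union of traversed
   edges, and set the compression ratio ρ_t = t / (n − |c(Ĝ)|), where
   |c(Ĝ)| is the component count — so the denominator is the number of node
   merges the walks performed. Convergent walks share edges, merge fewer
   nodes, and compress more.
4. **CF = Σ_{t=1}^{k} ρ_t.** Higher CF = more convergent, more compressive
   information routing.

The statistics panel covers node strength Ω, characteristic path length *L*,
geometric-mean weighted clustering *C*, Louvain modularity *Q* at resolution
γ (default 1.15), and normalized node/edge betweenness.

## Worked example

Generate a 128-node Watts–Strogatz graph and score it:

```python
from cflow import ModelSpec, generate, write_graph
write_graph(generate(ModelSpec(family="WS", n=128, mean_degree=8, seed=7)), "ws.tsv")
```

```
$ cf compute --graph ws.tsv --seed 42
{
  "cf": 2.390079365079365,
  "k": 7,
  ...
  "rho": [0.5, 0.2222, 0.3, 0.2857, 0.3571, 0.375, 0.35]
}
```

The periphery holds the k = 7 lowest-betweenness nodes. At load t = 1 the
single walk traversed two edges, merging two nodes (ρ₁ = 1/2); at t = 7 the
seven walks merged 20 nodes (ρ₇ = 0.35). CF = 2.39 is the summed compression
across the seven loads.

```
$ cf stats --graph ws.tsv
{
  "C": 0.4588, "L": 3.1892, "Q": 0.6251, "strength_mean": 8.0,
  "BC_mean": 0.01737, "EBC_mean": 0.00623, "n_nodes": 128, ...
}
```

A small-world profile: high clustering (C = 0.46), short paths (L = 3.19
hops), strong modular structure (Q = 0.63).

Other subcommands: `cf simulate` (degradation curves for WS/BA/ER/RL
families), `cf connectome` / `cf report` (time-series CSV → thresholded
correlation graph → full panel + CF), `cf compare` (pairwise rank-sum grids
with Bonferroni correction).

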