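# cardioergm

Statistical-mechanics analysis of arrhythmic risk in simulated cardiac
tissue: an excitable-lattice model of electrical conduction, a
causal-network abstraction of its dynamics, and exponential random graph
models (ERGMs) whose scalar *network potential* tracks the structural
transition from paced planar waves to self-sustaining reentry.

The package is aimed at computational physiologists and network
scientists who want a fully testable, end-to-end pipeline from a tissue
simulation to maximum-entropy network ensembles — without any external
data: the simulator is the data source.

## The model

**Tissue.** An `L x L` lattice of excitable cells arranged in fibers
(rows). Within-fiber neighbors are always coupled; transverse couplings
between adjacent fibers exist independently with probability `nu` (the
lateral coupling). Each cell fires for one time step, then is refractory
for a quenched period drawn uniformly from `tau_mean ± tau_jitter`. A
fraction of cells is *dysfunctional*: stimulation fails with probability
`epsilon` per event, seeding wavebreak. Pacemaker cells on the left edge
fire with period `T` and launch planar waves. At weak lateral coupling a
wavebreak curls into reentrant circuits — fibrillation-like activity in
which the excited-cell count exceeds `1.1 L` (one planar wavefront
excites exactly `L` cells).

**Network abstraction.** The excitation history is coarse-grained onto a
10 × 10 grid of nodes (3 × 3 neighborhood means). A directed edge
`i -> j` is retained when the lagged partial correlation between `i`'s
past and `j`'s present — conditioned on `j`'s own past (bivariate
Granger causality) — is significant; the edge weight is the signed
cross-correlation maximized over lags.

**ERGM.** For a directed graph G with sufficient statistics x(G),

    P(G | θ) = h(G) · exp(θᵀ x(G)) / Σ_G' h(G') · exp(θᵀ x(G'))

with statistics `edges`, `in2stars` (Σᵢ C(indegᵢ, 2)), `out2stars`,
`ctriads` (directed 3-cycles, one count per cycle) and optional
sender/receiver hub covariates. The reference measure h(G) carries
geometric constraints — here, a spatial support restricting candidate
edges to nearby nodes. θ is estimated by maximum pseudo-likelihood
(MPLE; logistic regression on change statistics) or Monte-Carlo maximum
likelihood (MC-MLE; importance-weighted likelihood-ratio ascent with a
Metropolis edge-toggle sampler), validated against exact enumeration for
n ≤ 5. The ERGM potential θᵀx(G) — the Boltzmann `−βH` of the network —
is the scalar summary compared across coupling regimes.

## Worked example

```python
from cardioergm import (
    LatticeConfig, simulate, arrhythmia_metrics, build_network,
    spatial_support, ERGMSpec, ReferenceMeasure, fit_mple,
)

cfg = LatticeConfig(L=100, nu=0.1, n_dysfunctional=500, horizon=3000, seed=5)
series = simulate(cfg)
m = arrhythmia_metrics(series)
print(f"time in arrhythmia: {m.time_in_arrhythmia:.3f}  "
      f"sustained reentry: {m.sustained_reentry}")

net = build_network(series, threshold_mode="significance")
mask = spatial_support(net.node_coords, radius=2.0, lattice_L=cfg.L)
net = net.restrict(mask)
fit = fit_mple(net, ERGMSpec(), ReferenceMeasure(support=mask))
for name, th, x in zip(fit.stat_names, fit.theta, fit.x_obs):
    print(f"  {name:10s} x = {x:8.0f}   theta = {th:+.3f}")
print(f"ERGM potential: {fit.potential:.1f}")
```

prints, for this weakly coupled (`nu = 0.1`) tissue:

```
time in arrhythmia: 0.618  sustained reentry: True
  edges      x =     1345   theta = -0.168
  in2stars   x =     9153   theta = +0.074
  out2stars  x =     8985   theta = +0.023
  ctriads    x =     2078   theta = -0.109
ERGM potential: 431.8
```

The same script at `nu = 0.9` (strong lateral coupling, planar
conduction) yields `time in arrhythmia: 0.000`, only 100 cyclic triads
instead of 2078, and a potential of 4084.3 — the cycle-rich functional
network of reentrant tissue is unmistakable at the level of a single
scalar.

The full experiment — sweep `nu`, fit per-`nu` networks, estimate the
transition — runs from the command line:

```
cardioergm sweep --replicates 5 --base-seed 0 --out results/
cardioergm simulate --nu 0.1 --seed 0 --out run.npz
cardioergm abstract --series run.npz --grid 10x10 --out net.graphml
cardioergm fit --network net.graphml --estimator mple
```

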