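# Methods

This note documents the models, estimators and numerical choices behind
`cardioergm`, in the spirit of a model-description appendix.

## Excitable-lattice tissue model

The tissue is a square lattice of `L × L` three-state excitable cells
(resting → excited for exactly one step → refractory countdown →
resting), updated synchronously. Rows are fibers: longitudinal
(within-row) coupling is always present, while each transverse coupling
between vertically adjacent cells exists with probability `nu`, drawn
once at construction (quenched disorder). Boundary conditions are
periodic top–bottom (a cylinder of fibers, so transverse reentry is not
suppressed by edge effects) and open left–right. A planar wave therefore
travels along fibers at one column per step, exciting exactly `L` cells
while in transit.

Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `L` | 200 | cells per side |
| `nu` | — | transverse coupling probability ∈ [0, 1] |
| `tau_mean ± tau_jitter` | 50 ± 5 | per-cell refractory period, uniform integer, quenched |
| `n_dysfunctional` | 2000 | dysfunctional cells (density 0.05 of the default lattice) |
| `epsilon` | 0.05 | per-stimulation excitation-failure probability of a dysfunctional cell |
| `pacing_period` | 220 | left-edge pacemaker period (steps) |
| `horizon` | 1000 | simulated steps |
| `arrhythmia_factor` | 1.1 | arrhythmia threshold multiplier on `L` |

The dysfunctional-cell default is a *density* of 0.05 — the same value
as the misfire probability, which is the operating point of this lattice
model class at which the reentry transition sits near `nu ≈ 0.14`. At
this density the expected number of defects sitting on a
transversally-isolated run of cells longer than a refractory period
(the structures capable of converting a misfire into a wavebreak) is of
order ten at `nu = 0.1` and essentially zero above `nu ≈ 0.2`, which is
what makes the transition sharp.

Misfire semantics: each stimulation of a dysfunctional resting cell is
an independent Bernoulli(1 − ε) excitation attempt within the step (so
`k` simultaneous stimulations fail together with probability ε^k). The
alternative reading — spontaneous ectopic firing of resting
dysfunctional cells at rate ε — is available as
`misfire_mode="ectopic"` but is not the default: excitation failure is
the established wavebreak mechanism in this model class, and ectopic
sources would make even strongly coupled tissue multi-wavelet, erasing
the planar/reentrant distinction the pipeline is built to detect.

Randomness is split into named streams (lattice disorder; misfire
draws) derived from the single top-level seed, so the quenched lattice
is reusable across dynamical replicates and every trajectory is bitwise
reproducible.

**Arrhythmia metrics.** A step is arrhythmic when the excited-cell
count exceeds `1.1 L`; a single paced wavefront contributes exactly `L`,
so only broken, multi-wavelet activity trips the threshold.
`time_in_arrhythmia` is the fraction of arrhythmic steps. *Sustained
reentry* requires every step of the final window (half a pacing period,
a pacing-free stretch) to be arrhythmic: activity that self-perpetuates
rather than dying out between beats.

## Coarse-graining and causal-network inference

Node activity is the mean of the binary fired/not-fired indicator over
a 3 × 3 block centered on each of 10 × 10 uniformly spaced sample
points (a graded encoding using the scaled refractory counter is
available). Edges are scored by bivariate Granger causality in
partial-correlation form: score(i→j) is the largest magnitude over lags
1..25 of the partial correlation between the source's lagged activity
and the target's present activity, conditioning on the target's own 25
lags (pseudo-inverse residualization, robust to rank-deficient pasts).
`max_lag = 25` covers the ~20-step conduction time between adjacent
sample points. Constant series score zero; series shorter than
`3 × max_lag` are rejected.

Two thresholding modes exist. The absolute mode retains edges with
score > 0.001 (a "0.1%" cut-off on the causality index); the
significance mode retains edges significant at level α = 0.001 under
the t-distribution null for a partial correlation,
Bonferroni-corrected for the lag search. The sweep pipeline defaults to
the significance mode: in these dynamics nearly every node pair clears
an absolute 0.001 (planar conduction synchronizes whole columns), which
yields ~98%-dense graphs at every coupling and a degenerate ERGM stage,
whereas the calibrated test yields networks whose density responds to
the physiology. Edge weights are signed cross-correlations maximized in
magnitude over lags 0..25 (ties to the smallest lag).

## ERGM

The model is the discrete exponential family
`P(G|θ) ∝ h(G) exp(θᵀx(G))` over simple directed graphs. Statistics are
evaluated on the 0/1 adjacency, or — in weighted evaluation mode — on
edge weights rescaled from [−1, 1] to [0, 1] by `(w+1)/2`, each motif
instance contributing the product of its edge weights. The cyclic-triad
convention is one count per directed 3-cycle (`trace(A³)/3`), so a
mutually complete triple carries two. Estimation is binary; weighted
statistics serve for evaluating the potential of an observed weighted
network. Full weighted-ensemble estimation (a joint density over
bounded weights) is out of scope.

**Reference measure.** `h(G)` encodes degree bounds and a candidate-edge
support mask, hard (indicator) or soft (`exp(−penalty · violations)`).
The pipeline's concrete choice is a spatial support: candidate edges
are limited to node pairs within 2 grid spacings (Chebyshev distance,
rows wrapped). This keeps the sufficient statistics local — remote
column-synchrony links otherwise dominate the counts and mask the
transverse-coupling signal the sweep is probing.

**Estimators.**

* *MPLE*: logistic regression of each dyad's edge indicator on its
  change-statistic vector (statsmodels), restricted to support dyads
  when a support is set. Exact for dyad-independent models (edges-only
  reduces to `logit(density)`). Perfect or quasi-separation (empty,
  complete, or otherwise degenerate graphs) is flagged and coefficients
  are reported from a box-bounded (±15) logistic fit rather than left
  divergent.
* *MC-MLE*: starting from the MPLE (or, when the MPLE is separated,
  from the density-matched independent-edge model), iterate: draw an
  ensemble at the current θ with the Metropolis single-edge-toggle
  sampler (chain initialized at the observed graph; thinning one
  proposal sweep, `n(n−1)`), then maximize the importance-sampling
  estimate of the log-likelihood ratio within a box trust region of
  half-width 0.5 around the sampling point. Convergence is the
  exponential-family moment condition: every simulated mean statistic
  within 5% (relative) of its observed value. Non-convergence after 20
  rounds is reported in diagnostics, not raised. Standard errors come
  from the inverse sampled covariance (the Fisher information).
* *Exact enumeration* (n ≤ 5): vectorized bitwise enumeration of all
  `2^{n(n−1)}` graphs provides exact probabilities, the exact MLE
  (convex optimization with analytic gradient) and the oracle against
  which the sampler (χ² over all 64 three-node graphs) and MC-MLE are
  tested.

## Sweep pipeline and transition estimate

For each (ν, replicate), with seeds derived deterministically from
(base seed, ν index, replicate): simulate → coarse-grain → causal
network → spatial-support restriction → MPLE fit → potential and risk
metrics. Failures are recorded per row and the sweep continues;
degenerate fits are flagged and excluded from potential aggregates. The
default ν grid {0.10, 0.12, 0.14, 0.16, 0.20, 0.30, 0.50, 0.70, 0.90}
is dense near the transition.

The transition coupling ν\* is the probability-0.5 midpoint of a
lightly ridge-penalized (λ = 1e−4) logistic fit of the per-run
sustained-reentry indicator on ν — the penalty keeps the fit defined
when the risk curve is a perfect step — with fallback to the largest ν
whose empirical reentry probability is ≥ 0.5, and an undefined flag
when no reentry occurs at all. Uncertainty is a percentile bootstrap
over replicates within each ν.

## What the synthetic data does and does not emulate

The simulator reproduces the phenomenology relevant to the network
analysis: fiber-anisotropic conduction, refractory-period dispersion,
defect-seeded wavebreak, and a sharp coupling-controlled transition
from paced planar waves to self-sustaining multi-wavelet reentry. It
omits membrane biophysics (ion-channel kinetics, action-potential
morphology, restitution), continuum electrotonic coupling, anatomy and
autonomic modulation. Passing tests therefore demonstrate that the
*pipeline* recovers structural transitions from spatiotemporal
excitation data of this class — not that it would do so unchanged on
clinical electrograms.

## Problem sizes and numerical choices in the test battery

* Transition check: full scale (200 × 200, horizon 1000), 8 replicates
  per ν — the per-run cost is ~4 × 10⁷ cell updates, a fraction of a
  second vectorized.
* Potential-discrimination check: a reduced lattice (L = 100, defect
  density 0.05 → 500 cells) with horizon 3000. The longer horizon keeps
  ~13 pacing cycles in the record; at the default 1000 (4–5 beats) a
  100 × 100 tissue initiates reentry in only about half the weakly
  coupled runs, which would compare two mixed ensembles instead of two
  regimes.
* Causal-recovery check: a 10-process lagged chain (autoregression 0.3,
  coupling 0.45) with the retention threshold 0.3 placed between the
  direct-link partial-correlation scale (~0.45) and the 2-hop-echo
  scale (~0.25); bivariate Granger scores are transitive by
  construction, so ancestor echoes — not noise — are the relevant
  false-positive mode.
* Parameter-recovery check: n = 20, θ = (−1.0, 0.2) for
  (edges, ctriads), a regime with informative cyclic-triad counts
  (~170 per graph) that stays clear of the degenerate complete-graph
  phase a large positive cycle parameter induces.
* Ties, degeneracies: cross-correlation ties resolve to the smallest
  lag; constant series produce zero scores rather than NaNs; empty and
  complete graphs are legal MPLE inputs that return flagged, bounded
  estimates.

## Known limitations

* Bivariate (pairwise) Granger conditioning only; full multivariate or
  PC-stable conditioning is out of scope, so inferred networks contain
  transitive edges by design.
* MC-MLE on near-boundary observed statistics (convex-hull edge) stalls
  at large |θ| and reports non-convergence rather than detecting the
  boundary case explicitly.
* Weighted ERGM support is evaluation-only (weighted statistics and
  potential of the observed network); the sampler and estimators are
  binary.
* The sustained-reentry classifier is a windowed threshold rule; very
  slow reentrant rotors with excited counts hovering near `1.1 L` could
  be misclassified at the margin.
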