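# Methods

## Model

`hmmselect` models consecutive-time expression differences, not expression
levels. For a design with T time points, Z conditions and R replicates,
each gene g in each condition contributes one observation sequence
(Δg₁, …, Δg_{T−1}) with Δg_t ∈ ℝ^R the replicate vector of differences
between time t+1 and time t. A two-state hidden Markov chain over
{N (no change), C (change)} generates each sequence; state k emits from a
multivariate normal N(0, Σ_k) over the replicate dimension.

Assumptions worth stating explicitly:

* **Feature independence.** All G×Z sequences are treated as independent
  draws from one shared chain, which is what makes estimation feasible with
  few samples. Co-regulation between genes is ignored by design.
* **Zero emission means.** Means are constrained to the zero vector by
  default (`EMConfig.zero_mean`). The model cares about the magnitude of
  change; letting the means float adds 2R parameters that short experiments
  cannot support, and empirically fitted means sit at zero anyway. A config
  switch frees them.
* **Already-normalized input.** The pipeline expects a normalized
  (log-scale) expression matrix; normalization, batch correction and count
  modelling are out of scope.
* **No significance machinery.** There is deliberately no p-value or hard
  cut-off anywhere: the change/no-change call at each step is the Viterbi
  decision under the fitted transition and emission probabilities, so the
  estimated state variances are the operative "thresholds".

## Estimation and decoding

Parameters (π, A, Σ_N, Σ_C) are estimated by Baum–Welch over all pooled
sequences, with the forward–backward recursions carried out in log space
(log-sum-exp), vectorized across sequences. Numerical and procedural
choices:

* **Initialization.** π = (½, ½); A = [[0.9, 0.1], [0.1, 0.9]]; Σ_k
  initialized to the pooled delta variance scaled by 0.25 (N) and 2.0 (C)
  times the identity. Restart 0 uses exactly this start; additional
  restarts (default 3 total) jitter the variance scales log-normally
  (σ = 0.5) and the transition rows with positive uniform noise, all from a
  seeded generator. The best final log-likelihood wins.
* **Convergence.** Stop when the relative change in total log-likelihood
  falls below `tol` (default 1e-6) or after `max_iter` (default 500)
  iterations. The trace is checked to be non-decreasing (tolerance 1e-8
  per step); a decrease — possible only when the variance floor engages —
  raises a warning, never passes silently.
* **Covariance structure.** Full R×R by default (`covariance="diag"`
  available). After every M-step the covariance is symmetrized and its
  eigenvalues floored at `var_floor` (1e-8), which keeps EM alive on
  degenerate inputs such as all-constant genes; π and the rows of A are
  renormalized exactly onto the simplex.
* **State identifiability.** EM does not label states. After fitting, the
  state with the larger covariance trace is relabelled C; this matches the
  semantics that the change state is the high-dispersion one.
* **Viterbi ties.** Exact ties in the dynamic program are broken toward N
  at every step and at the terminal argmax. This is conservative: a gene is
  never called changing on a coin flip. Ties have measure zero for generic
  data but occur for exactly constant genes (all emissions identical), which
  consequently decode to the null path and are never selected.
* **Shuffling.** Feature order is randomly permuted (seed 1729 by default)
  before fitting, identically across conditions so per-gene paths stay
  aligned; results are reported in the original order. With fully pooled
  batch EM the permutation only changes floating-point summation order, but
  it is kept as a guard for any order-sensitive variation of the fit.

Selection then compares decoded paths. The default `whole-path` rule
requires the control path to be entirely flat; the alternative `per-step`
mode counts a case change only at steps where the control is simultaneously
flat, for users who prefer a stepwise reading of the case/control
comparison. Without a control, any non-flat gene is kept.

Ranking has no canonical score combination, so none is invented: the
default order is lexicographic (changes ↓, magnitude ↓, replicate
disagreement ↑, gene id), and per-score ranks are written alongside. Note
the replicate score *formula* grows with disagreement while its intent is
"consistent replicates are better"; the raw sum is stored and smaller is
treated as better in ranking.

## The simulator

`simulate_dataset` generates data from the same model family the pipeline
fits, with known ground truth. Defaults define the reference study
conditions: 10,000 transcripts, 6 time points, 3 replicates, 10% of
case-group features perturbed, emission sds 1.0 (C) and 0.2 (N), white
replicate noise of sd 0.1 (all in log-expression units).

* Control features and unperturbed case features follow the all-N path.
* Perturbed case paths are sampled from a row-stochastic transition matrix,
  default [[0.9, 0.1], [0.5, 0.5]] started from its stationary
  distribution, rejected until they contain at least one C. The default
  makes the null state persistent and the change state transient — changes
  are sparse, short excursions, which is the regime the method targets.
* Given a path, each replicate's deltas are drawn independently from the
  state Gaussian; profiles are rebuilt by cumulative summation from a
  baseline offset uniform on [2, 12] (removed again by differencing, but it
  makes fixtures realistic); white measurement noise is added per replicate
  and time point.

Because measurement noise enters each difference twice, a no-change delta
has marginal sd √(0.2² + 2·0.1²) ≈ 0.245, and that — not 0.2 — is what a
perfectly fitted emission sd estimates. Adjacent deltas also share one
noise term (covariance −0.01), a mild violation of the model's conditional
independence over time that the simulator intentionally retains.

What the simulator does **not** emulate: RNA-seq count noise and library
size effects, microarray probe effects, gene–gene correlation, and
replicate-specific batch shifts. Passing the simulation checks therefore
shows the estimator and decision rules are correct under the model's own
assumptions, not that those assumptions hold for any particular real
dataset.

## Problem sizes used in the checks

The recovery checks run the full pipeline at the reference design
(10,000 × 6 × 3) over five seeds — about five seconds per seed on one CPU —
and the expected operating point is ≈0.87 sensitivity / ≈0.99 precision
under the default generator. Oracle-equivalence checks compare Viterbi and
the forward likelihood against exhaustive enumeration over all 2^(T−1)
paths for lengths up to 10 and up to 3 replicates; EM property checks use
100 small random datasets, and parameter-recovery checks use 3,000-feature
simulations, sizes at which the estimates are already stable.

## Known limitations

* Two states cannot distinguish up- from down-regulation at the state
  level; the sign lives in the deltas themselves.
* Unequal replicate counts across conditions cannot form a fixed-width
  emission vector; such designs are collapsed to per-time means (R = 1)
  with a warning, losing the replicate-quality score (it is zero for R = 1).
* A relevant call has no attached error rate; the selection is a decision
  rule, not a test, and features with tiny but consistently decoded changes
  are kept by design.
* Missing values are rejected, not imputed: imputation would silently
  distort the delta statistics the whole method runs on.
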