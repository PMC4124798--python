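# Methods

This note documents the models, numerical choices, and validation design of
`smtl` at the level a maintainer or reviewer needs; the README gives the
user-facing overview.

## Model and assumptions

The pipeline assumes a binary classification problem whose classes are
mixtures of a small number of Gaussian-like peaks ("subclasses") in feature
space, with only a sparse subset of features carrying class or subclass
signal. Under that assumption a single linear regression of the ±1 label
(lasso-style single-task selection, STL) conflates the peaks of a class:
within-class multimodality inflates the residual variance of every
informative feature and can cancel class-mean differences entirely. The
subclass-based multi-task method (SMTL) instead:

1. clusters each class separately with K-means (Lloyd's algorithm,
   squared-Euclidean objective `J(C) = Σ_k Σ_{x∈c_k} ‖x − μ_k‖²`);
2. assigns each subclass a sparse code — original label first, then a ±1
   one-hot subclass indicator — so that same-class codes sit at squared
   distance 2 and cross-class codes at 6;
3. regresses the resulting N×S code matrix Y on X under an ℓ2,1 row-sparsity
   penalty, so each subclass contributes its own regression task but
   features are selected jointly;
4. classifies on the surviving features with a linear SVM (single kernel, or
   a convex combination of per-modality linear kernels).

The first task (column 1 of Y) is the original binary problem; the remaining
tasks are one-vs-rest subclass problems. `K(+) = K(−) = 1` is retained as a
legal configuration: its three-column Y still differs from the single-task
formulation, so the grid search may choose it without collapsing to STL.

## Solvers

Both penalized problems are written exactly as

    min_w ‖y − Xw‖² + λ₁‖w‖₁        (single-task)
    min_W ‖Y − XW‖²_F + λ₂‖W‖_{2,1}  (multi-task)

with no ½ or 1/N factor on the loss; every threshold below follows from
this convention (e.g. the smallest penalty with an all-zero solution is
`2·max_i ‖(XᵀY)_i‖₂` for the multi-task problem and `2‖Xᵀy‖_∞` for the
single-task one).

The optimizer is FISTA with a monotonicity safeguard: a gradient step on the
smooth term (`∇ = 2Xᵀ(XW − Y)`, step `1/L`, `L = 2σ_max(X)²` computed from
the smaller Gram matrix) followed by the prox of the penalty — row-wise
group soft-thresholding `(1 − τ/‖v_i‖)₊ v_i` for ℓ2,1, elementwise soft
thresholding for ℓ1. If finite-precision arithmetic violates the curvature
majorization, L is doubled (backtracking); if an accelerated step would
increase the objective it is rejected and the momentum restarted, so the
recorded objective trace is non-increasing by construction. Convergence is
declared when the relative objective change falls below `rel_tol`
(default 1e-8 for standalone use, 1e-5 inside the CV pipeline where only
the selected support matters).

Selected features are rows with `‖w^i‖₂ > tol · max_i ‖w^i‖₂`
(`tol = 1e-6`): proximal iterates are exactly zero only at the prox, so a
relative threshold is robust across float regimes. An empty support is a
flagged, legal outcome; the pipeline scores such a trial at the
majority-class rate so model selection routes around it.

Validation uses independent oracles that share no code with the solvers:
block coordinate descent with closed-form row updates for ℓ2,1, elementwise
coordinate descent for ℓ1, both run to ~1e-14 relative tolerance. The FISTA
objectives agree with these oracles to ~1e-12 relative on random instances
— far inside the 1e-4 band the tests assert.

## Penalty grids and scale

The hyperparameter grids default to K ∈ {1..5}, C ∈ {2^−10..2^5}, and the
nine-point sparsity grid {0.001, 0.005, 0.01, 0.05, 0.1, 0.15, 0.2, 0.3,
0.5}. Because the loss carries no 1/N factor, an absolute penalty of this
magnitude would be negligible at realistic sample sizes (the critical
penalty is O(N)), so the pipeline interprets grid values as *fractions of
the training fold's critical penalty*, the smallest value whose solution is
identically zero. This makes one grid meaningful across data scales and
matches how packaged solvers with normalized regularization parameters are
commonly driven. The standalone solver functions take absolute penalties.

## K-means details

- k-means++ seeding (via scikit-learn's `kmeans_plusplus`), 10 restarts by
  default, best objective kept. The Lloyd loop itself is in-package because
  its internals are contractual.
- Assignment ties go to the lowest cluster index (argmin semantics), so runs
  are deterministic under a fixed seed.
- If an update empties a cluster, it is re-seeded at the sample farthest
  from its assigned center. This strictly decreases the objective and keeps
  exactly K non-empty subclasses, which the encoding requires.
- Convergence: identical assignments between iterations, or 300 iterations.
- The per-iteration objective is asserted non-increasing on every run
  (tolerance 1e-9 relative); a violation is a bug, not a warning.
- In the pipeline a single K is shared by both classes by default (the grid
  lists one K), capped at each class's training size;
  `ExperimentConfig(independent_K=True)` searches K(+) and K(−) over the
  full product grid instead, with ties broken toward the smaller total
  subclass count.

## Cross-validation protocol

Outer stratified 10-fold CV (per-class partition into near-equal folds
without replacement); inner stratified 5-fold CV on each outer-training fold
scores every grid point by mean validation accuracy, running the full
pipeline (standardize → cluster → encode → solve → select → SVM) from
scratch inside each inner fold. Ties break deterministically: smaller K
(simpler subclass structure), then larger penalty (sparser), then smaller C.
The winner is refitted on the whole outer-training fold and evaluated once
on the held-out fold, so no test label ever influences selection. Outer
folds are shared across compared methods, making the paired t-test on
fold-wise accuracies genuinely paired. Features are z-scored with
training-fold statistics only (the penalties are scale-sensitive); the
switch is `ExperimentConfig(standardize=False)` if raw units are wanted.

Reported metrics: ACC, SEN, SPEC, BAC = (SEN+SPEC)/2, and AUC from SVM
decision scores (no probability calibration), each computed per outer fold
and averaged; the SD accompanying ACC is across the 10 folds. A class absent
from a test fold leaves SEN or SPEC NaN — never silently zero — and NaNs
are excluded from averages. AUC uses the rank definition (probability a
random positive outscores a random negative, ties ½).

## Henze–Zirkler diagnostic

The multipeak assumption is probed with the Henze–Zirkler multivariate
normality test: the weighted L2 distance between the empirical
characteristic function of the standardized sample and the standard normal
one, with smoothing parameter `b = ((n(2p+1))/4)^{1/(p+4)}/√2` and the
log-normal approximation for the null distribution (biased sample
covariance). The implementation is written from the original constants and
cross-checked in the tests against an independent implementation
(pingouin's) to ~1e-10, and calibrated by simulation: type-I error ≈ 0.05
on Gaussian data, power > 0.9 against two peaks 6 within-peak SDs apart
(n = 500, p = 3, 200 replicates).

## Synthetic cohorts

`smtl.synthetic` draws each sample by picking a peak from its class's
mixture, adding isotropic Gaussian noise (`within_peak_sd`) on the
informative features, and filling all other features with standard normal
noise identical across classes — so any selected noise feature is a
verifiable false positive, and peak memberships are known. Isotropic
within-peak covariance is the default because it matches K-means's implicit
assumption, keeping parameter-recovery tests clean; a full-covariance mode
is deliberately out of scope.

Preset scenarios (all with unit within-peak SD):

- **unimodal** — 40+40 samples, 60 features, 10 informative with a ±0.35
  class-mean shift, one peak per class. Joint signal ≈ 2.2σ, a moderate
  problem where subclass modeling has nothing to exploit.
- **bimodal** — 50+50 samples, 100 features, 10 informative, two peaks per
  class at `class_shift ± peak_offset` = 0.35 ± 1.4 on complementary halves
  of the informative set (mirrored for the negative class). Every
  informative feature then has a weak marginal class effect (≈ 0.4σ after
  standardization) while the within-class peaks sit ≈ 8σ apart, and the
  classes remain linearly separable through the summed informative score
  with an accuracy ceiling near 0.75 — comparable to the hardest
  conversion-prediction problems this methodology targets. This is the
  heterogeneous-subtype regime the subclass method exists for: single-task
  selection is statistically unreliable there, subclass-task signal is
  strong.
- **adni-like** — 51/52 samples, 93+93+3 modality blocks, 3 vs 2 peaks with
  randomly drawn (but fixed) peak signatures; exercises multimodal
  bookkeeping and multi-kernel fusion, not a distributional imitation of
  any real cohort.
- **null** — no informative features; every pipeline must score at chance.

What passing tests on these cohorts do *not* show: robustness to
correlated noise features, anisotropic or heavy-tailed peaks, outliers, or
real ROI covariance structure — the generator makes none of those, by
design.

## Problem sizes in the validation suite

The simulation study in the acceptance tests runs 20 generator seeds per
scenario with reduced grids (K ∈ {1,2,3}, penalty fractions {0.05, 0.15,
0.3}, C ∈ {0.25, 1, 4}) — the package's chosen desk-scale configuration,
exposed as `ExperimentConfig.reduced()`. Solver-oracle agreement uses 50
random (30×20, 4-task) instances; K-means optimality uses 100 instances of
up to 8 points against exhaustive enumeration of all 2-partitions;
normality calibration uses 200 Monte-Carlo replicates per condition. All
randomness flows from named substreams of a single master seed
(`component_rng`), so any stage reproduces in isolation.

## Known limitations

- Lloyd's algorithm is a local optimizer; with 10 restarts a small fraction
  of tiny instances still miss the global optimum (the tests allow 5%).
- The ℓ2,1 path is evaluated on a fixed grid; no path algorithm or
  continuation beyond warm starts across the grid.
- Binary problems only; the code construction has no multi-class extension
  here.
- The multi-kernel weight search is exhaustive on the simplex lattice and
  scales combinatorially with the number of modalities (66 points for 3
  modalities at step 0.1; fine for the intended 2–3).
- Whether C should be searched jointly with the modality weights is an open
  protocol question; the implementation searches jointly, and callers can
  pin C by passing a singleton grid.
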