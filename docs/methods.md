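# Methods

## Scope and assumptions

`margincad` implements a block-feature, large-margin classification pipeline
for spatially normalized functional brain volumes.  It assumes its inputs
are already registered to a common grid (default 95×69×79 voxels of
2×2×2 mm): spatial normalization, reconstruction and scanner modeling are
upstream concerns and are deliberately outside the package.  All analysis
code works in 0-based voxel indices; millimetres appear only at the NIfTI
I/O boundary.

AD (any severity) is the positive class throughout; every binary tie —
kNN votes, EBC energy gaps, SVM decision values at exactly zero — resolves
to the negative (CTRL) label, biasing against false alarms in a diagnostic
setting.

## Intensity normalization

Two per-subject rules make intensities comparable across subjects:

* **SPECT**: divide by I_max = the mean of the top 3 % of voxel
  intensities.  Top-k selection takes `ceil(fraction · n_voxels)` voxels
  (at least one), ranking by value with ties broken by voxel index.  The
  rule is idempotent and leaves the brightest tissue at level 1.
* **PET**: a 50-bin equal-width histogram over [min, max] of the volume
  (computed on the whole volume, background included); voxels below the
  lower edge of the 10th bin (1-based) are discarded as out-of-brain, and
  I_max is the mean of the top 0.1 % of the survivors.  Reading "the 10th
  bin intensity value" as that bin's *lower* edge is the conservative
  choice and both the bin count and the bin index are configurable.

Normalized volumes are dimensionless with reference level 1; a constant
volume is a contract error for the PET rule (no dynamic range) but not for
the SPECT rule.

## Masking and NMSE features

The activation mask keeps voxels whose mean-control intensity *strictly*
exceeds half the maximum of the mean image, making masking invariant to
global intensity scaling.  Blocks of side 5 (configurable, odd) tile the
volume on a stride-of-side lattice; a block is kept iff its center voxel is
mask-true and the cube lies in bounds, so blocks never overlap.  Block
voxels outside the mask still contribute to the NMSE sums — the mask gates
*which* blocks exist, not which voxels are summed.  Blocks whose control
energy Σf² is zero are degenerate and dropped for the whole cohort.

The per-block NMSE sums squared deviations of the subject from the mean
control image, normalized by the control energy: 0 for a subject matching
the control average, ≈(1−s)² for a uniform multiplicative deficit s, 1 for
a missing block.

The t-test ranking uses the pooled-variance two-sample statistic with
sample variances (n−1 denominators).  Zero pooled variance with equal class
means gives |t| = 0; with unequal means the feature separates the classes
exactly and ranks first (infinite-|t| convention).  No multiple-testing
correction is applied: the statistic is a ranking filter, not an inference.
The default of 200 selected blocks follows the pipeline's standard
operating point; whether selection happens per training fold (the default
here) or once globally is a leakage question, not a modeling one — see
Evaluation.

## Reduction

* **PCA** is computed by SVD of the centered data; eigenvalues are those of
  the sample covariance (ddof = 1), and a deterministic sign convention
  (largest-magnitude loading positive) makes results reproducible.
* **Kernel PCA** uses the Gaussian kernel exp(−‖x−y‖²/(2σ²)) with explicit
  double-centering of the kernel matrix.  σ defaults to the median pairwise
  training distance.  Dual coefficients are scaled v/√λ, which makes
  linear-kernel KPCA projections coincide exactly with PCA scores — the
  module's cross-validation anchor; requesting components beyond the
  numerical rank of the centered kernel is an error rather than silent
  noise amplification.
* **PLS (SIMPLS)** deflates the cross-product matrix S = XᵀY (never the
  data): each weight w_j is the first left singular vector of the deflated
  S_j, scores t_j = X_c w_j are stored unit-norm, loadings p_j = X_cᵀ t_j
  are taken against the *undeflated* centered X (deflation lives entirely
  in S).  Y is a single centered ±1 column (+1 = AD).  If S deflates to
  zero the fit stops early with a warning and returns fewer components.

  Projection of new samples uses the unit-norm weight matrix W:
  z = (x − x̄)ᵀW.  The alternative — rescaling each column so training
  projections reproduce the unit-norm scores T — inflates late,
  noise-dominated components to the same scale as the leading ones, and in
  cross-validation that measurably destroys generalization: downstream
  metric learning and SVMs latch onto in-sample noise directions whose
  out-of-sample spread is much smaller, displacing held-out subjects
  relative to the training classes.  With W-projection the later
  components keep their natural (small) scale.  The T-reproducing rotation
  is still available as `PlsModel.x_rotation` for diagnostics.
* **Kernel PLS** is SIMPLS on kernel-PCA coordinates (the KPCA trick),
  mirroring how the kernel variant of LMNN is built.
* `variance_explained` reports per-component percentages of total X
  variance: eigenvalue/trace for PCA, ‖p_j‖²/‖X_c‖²_F for PLS (exact
  because SIMPLS scores are orthonormal).  Six components are the default
  operating point; past six the explained variance flattens on data of
  this kind.

## LMNN

Target neighbors are the k nearest same-class samples under Euclidean
distance in the *input* space, fixed at initialization (the loss is defined
over a fixed j→i relation; no re-assignment passes).  Self-matches are
excluded by index, so exact duplicates remain eligible.  Defaults: k = 3
target neighbors, μ = 0.5 — neither is canonical, both are configurable and
matter mostly through the push term's margin pressure.

The loss and analytic gradient re-scan hinge-active triplets exactly every
iteration (cohorts are ~10² samples; no approximation is needed).  At hinge
kinks the subgradient 0 is used.  M = LᵀL is adopted (the only form
consistent with D_M(x_i,x_j) = ‖L(x_i−x_j)‖²).

Optimization is plain gradient descent over L with an adaptive step:
accepted steps grow the step ×1.1, rejected steps revert and halve it;
termination on relative accepted-loss change < 1e−7 or 200 iterations.  The
accepted-iterate loss trace is non-increasing by construction and is
returned for diagnostics.  Square transforms start from the identity;
rectangular (LMNN-RECT) transforms start from the top-r PCA eigenvectors of
the training matrix — both deterministic.  Optimizing L directly is
non-convex; a local minimum is accepted, which matches how the transform is
used (as a learned feature map, not a certified optimum).

Kernel LMNN runs the same optimizer on kernel-PCA coordinates; with a
linear kernel the coordinates are a rotation of the centered inputs and the
identity-initialized descent is rotation-equivariant, so the loss
trajectory reproduces plain LMNN — a property the tests exploit.  The KPCA
component count feeding LMNN defaults to the same 6 as the linear
pipelines.

## Classifiers

* **kNN** (default k = 3, odd to avoid binary ties): Mahalanobis kNN
  factorizes M = FᵀF by eigendecomposition (negative rounding eigenvalues
  clipped to zero) and reduces to Euclidean kNN on F-transformed data.
  Even-k ties fall back to the single nearest neighbor.  The ROC score is
  the signed vote fraction.
* **EBC** scores each candidate label ŷ by three terms: squared distances
  from the query to its k nearest ŷ-labeled training points (its
  hypothetical targets, chosen in the learned space); hinge losses of
  differently labeled training points inside the query's target margins;
  and hinge losses where the query invades the stored target margins of
  differently labeled training points.  Margin constant 1, equal term
  weights (the μ-weighting of training is not reused — nothing suggests the
  classification energy re-balances the terms).  The ROC score is the
  energy advantage of the AD label.
* **SVM**: soft-margin dual SVM via scikit-learn's SVC.  Defaults C = 1,
  RBF γ = 1/(n_features · Var X), polynomial degree 3 with coef0 = 1,
  quadratic = degree 2.  The ROC score is the signed decision value.

## Evaluation

Every data-dependent stage — mask, NMSE reference image, t-test selection,
reduction, LMNN, classifier — is re-fit inside each training fold; the test
fold is only ever projected and scored.  Fold models expose a parameter
fingerprint (SHA-256 over all fitted arrays) so leakage can be asserted
directly: permuting held-out labels must reproduce bit-identical models.

Folds are **stratified** random splits by default.  Plain random folds make
the training-fold class majority the exact complement of the test fold's;
with ~80 subjects and a flexible pipeline that degenerates to a
training-majority predictor on signal-free data, this drives pooled null
accuracy systematically *below* chance (measured ≈ 32–39 % on null
phantoms) — an estimator artifact, not a property of the data.
Stratification removes it; the plain splitter remains available
(`stratified_folds=False`, `kfold_split`).

Metrics are computed on pooled confusion counts (per-fold averages are also
reported); zero-denominator metrics are reported as missing, never as 0.
ROC curves come from a threshold sweep with simultaneous tie steps and
trapezoidal AUC (equivalently the normalized Mann–Whitney U, which the
tests check independently).  If a split leaves a training fold
single-class, the split is re-drawn with a derived seed up to 20 times
before aborting.

## Synthetic phantoms

A phantom subject is

  baseline · brain_indicator · gain · Π region_deficits + smoothed noise,

clipped at zero and stored float32.  Defaults: 95×69×79 grid, ellipsoidal
brain (semi-axes 40×29×33 voxels), baseline 100, per-subject lognormal gain
σ = 0.1 (global tracer-dose/uptake variation, removed exactly by the
intensity normalization), additive Gaussian noise σ = 10 blurred with a
2-voxel-FWHM Gaussian (≈3 % effective noise, emulating
resolution-correlated scanner noise; the *signal* is not blurred so
ground-truth region edges stay crisp for overlap scoring).  Deficits are
multiplicative — perfusion and metabolism scale with intensity — with
factors 0.85/0.75/0.60 for AD1/AD2/AD3 and three regions placed to mimic
the qualitative AD topography (bilateral temporo-parietal plus posterior
midline).  Severities are apportioned by largest remainder from a
mild-heavy mix (30:22:4) resembling a clinical referral population, then
shuffled.  Cohorts are bit-reproducible from (spec, seed) via spawned
seed sequences.

What the phantom does *not* emulate: anatomical variability between
subjects (every brain is the same ellipsoid), partial-volume and
attenuation effects, label noise, and within-class biological heterogeneity
of perfusion.  Class separations on the phantom are therefore much cleaner
than on clinical data — the default cohort is classified perfectly —
so phantom results validate the *machinery* (feature recovery, metric
learning, leakage-free evaluation, null behavior at chance), not clinical
performance levels.

## Problem sizes and runtime choices

The shipped test and acceptance runs use the full 95×69×79 grid with
40 CTRL + 40 AD subjects for phantom-recovery and cross-validation checks
(the package's standard cohort scale), a 30×24×26 mini-phantom for unit
tests, and n ≤ 24 toys for brute-force LMNN oracles.  Null-cohort behavior
is summarized over 10 seeds in the tests and 5 seeds in the acceptance
script, reported as the mean pooled accuracy (a single 80-subject pooled
accuracy has binomial σ ≈ 5.6 %, so individual seeds are only checked
against a wide null band).

## Known limitations

* The EBC is specified verbally in the literature this follows; the
  three-term instantiation above is this package's documented reading.
* LMNN's objective is non-convex in L; different initializations can reach
  different local minima (initializations are deterministic here).
* The PET histogram convention (whole-volume, lower-edge threshold) is one
  of several defensible readings; both knobs are exposed.
* `variance_explained` is defined for PCA and PLS; for kernel models the
  quantity refers to the kernel-feature space and is not reported.
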