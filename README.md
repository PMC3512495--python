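# margincad

Large-margin computer-aided diagnosis (CAD) for functional brain volumes
(SPECT / PET), aimed at discriminating Alzheimer's-disease (AD) patterns of
regional hypoperfusion / hypometabolism from controls at small sample sizes.
It is written for methods researchers in nuclear-medicine image analysis who
need a complete, testable reference pipeline — including a synthetic phantom
generator, so every stage can be exercised and validated without clinical
data.

## The method

Starting from spatially normalized, intensity-normalized 3D volumes with
binary labels (CTRL negative, AD positive):

1. **Activation mask.** The control subjects are averaged into `sm(x,y,z)`;
   the mask keeps the voxels with `sm(x,y,z) > 0.5 · max(sm)`.
2. **NMSE block features.** The masked volume is tiled into non-overlapping
   5×5×5-voxel blocks; each subject *p* and block centered at (x, y, z) gets

   `NMSE_p(x,y,z) = Σ_block [f − g_p]² / Σ_block f²`

   where `f` is the mean control image and `g_p` the subject's image.
3. **Feature selection.** Blocks are ranked by the absolute pooled-variance
   two-sample t statistic between classes; the top 200 are kept.
4. **Reduction.** PCA, Gaussian-kernel PCA, PLS via the SIMPLS algorithm
   (deflating the cross-product matrix S = XᵀY), or LMNN-RECT (below), down
   to 6 components by default.
5. **LMNN metric learning.** A linear transform **L** minimizes

   `ε(L) = (1−μ) Σ_{j→i} ‖L(x_i−x_j)‖² + μ Σ_{i,j→i} Σ_l (1−y_il)[1 + ‖L(x_i−x_j)‖² − ‖L(x_i−x_l)‖²]₊`

   pulling each sample toward its k same-class target neighbors and pushing
   differently labeled impostors beyond a unit margin.  The induced
   Mahalanobis metric is M = LᵀL.  A rectangular **L** (LMNN-RECT) doubles
   as a supervised reducer; run on kernel-PCA coordinates the same machinery
   gives kernel LMNN.
6. **Classification.** Kernel SVMs (linear / quadratic / polynomial / RBF),
   kNN under the Euclidean or learned Mahalanobis metric, or the
   energy-based classifier (EBC), which assigns the label minimizing the
   LMNN-style energy.
7. **Evaluation.** Stratified 10-fold cross-validation with every
   data-dependent stage re-fit per training fold; pooled accuracy,
   sensitivity TP/(TP+FN), specificity TN/(TN+FP), ROC and AUC.

The phantom generator plants multiplicative intensity deficits (severity
factors 0.85 / 0.75 / 0.60 for mild / moderate / severe disease) in
bilateral temporo-parietal-like and posterior-midline regions of an
ellipsoidal brain, with per-subject gain and smooth noise, and records the
ground truth for recovery scoring.

## Worked example

```python
import margincad as mc

spec = mc.default_ad_spec()
cohort, truth = mc.generate_cohort(spec, n_ctrl=40, n_ad=40, seed=7)

config = mc.PipelineConfig(reduction="pls", n_components=6,
                           lmnn_transform=True, classifier="svm_linear",
                           folds=10, seed=7)
report = mc.run_pipeline_cv(cohort, config, seed=7)
print(f"pipeline : {report.pipeline_id}")
print(f"accuracy : {report.accuracy:.2f} %")
print(f"sensitivity: {report.sensitivity:.2f} %")
print(f"specificity: {report.specificity:.2f} %")
print(f"AUC      : {report.auc:.4f}")
```

prints

```
pipeline : nmse-pls-lmnn-svm_linear
accuracy : 100.00 %
sensitivity: 100.00 %
specificity: 100.00 %
AUC      : 1.0000
```

i.e. on the default phantom (deficits of 15–40 % against ~3 % effective
noise) the NMSE→PLS→LMNN→SVM pipeline recovers the planted class structure
perfectly, while the same pipeline on a null phantom (severity factor 1)
stays at chance — the two calibration points that bracket a working
implementation.  Real cohorts, with label noise and anatomical variability,
sit between these extremes.

The same run is available from the shell:

```sh
margincad simulate --n-ctrl 40 --n-ad 40 --seed 7 --out cohort/
margincad evaluate --manifest cohort/manifest.csv --pipeline pls-lmnn-svm \
    --folds 10 --seed 7 --out report/
```

`margincad --help` lists the remaining subcommands (mask, features, reduce,
train, roc) and every default.

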