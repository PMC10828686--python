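# Methods

## Problem setting

Renal-cell-carcinoma prognosis from preoperative CT. Two observations drive
the design: (i) the ISUP nuclear grade (1–4) of an RCC tumor is a strong
clinical predictor of mortality, and (ii) a network trained to predict that
grade from a CT crop learns tumor morphology features that carry prognostic
signal. The package therefore trains a 3D grading classifier first and then
fits a survival model on the classifier's pooled features, rather than
regressing survival directly from images.

## Preparation pipeline

Order: kidney extraction → RAS reorientation → resize → z-score
normalization → tumor-channel concatenation.

* Kidney extraction crops the axis-aligned bounding box of each connected
  kidney(+tumor) component; margin defaults to 0 voxels so the context
  around the tumor is decided by the segmentation, not a heuristic. When a
  scan shows two kidneys, the default policy keeps those whose box contains
  tumor voxels (both, as separate samples with the same label, if both do);
  `left` / `right` / `both-separately` policies are available because which
  kidney(s) the reference protocol used is not knowable from its
  description.
* Reorientation uses the NIfTI affine via nibabel and is idempotent.
* Images are resampled trilinearly, masks with nearest neighbor (label set
  preserved exactly); both channels always pass through the same spatial
  operator. Target size defaults to 128³; tests use 32³, which is the
  minimum the backbone's stride product admits.
* Normalization is per-volume z-scoring with the population (ddof = 0)
  standard deviation, applied after resizing. A cohort-level alternative
  would couple samples and is intentionally not the default.
* The tumor mask is binarized and stacked as channel 1 so the classifier is
  steered toward the tumor's size, position and surface.

## Class-aware augmentation

Grade counts in the emulated cohort are highly imbalanced (roughly
13% / 49% / 27% / 11%). Each grade gets its own augmentation factor
`max(0, ceil(target/count) − 1)` with `target = 500`, so minority grades are
oversampled to ≈500 while the majority grade is barely augmented.
Position transforms (affine shear `(0, 0.5, 0)`, horizontal/vertical flips
at p = 0.5, in-plane rotation uniform in ±90°) act jointly on both channels,
with the mask re-binarized afterwards. Noise transforms act on the image
channel only: additive Gaussian N(0, 1); a single k-space spike whose
log-magnitude is drawn from (10, 13) at a random non-DC frequency; and Gibbs
low-pass truncation removing the top `alpha ∈ (0.6, 0.8)` fraction of radial
frequencies (applied with probability 1). Three conventions had to be fixed
(shear-matrix layout, spike = replaced k-space coefficient, alpha = removed
high-frequency fraction); they are documented in the module docstring.
Augmented copies of a patient never leave that patient's train/val/test
split.

## Grading network

An EfficientNet-style MBConv backbone with all 2D operations inflated to 3D:
cubic kernels of the original 2D size, strides replicated on the third axis,
squeeze-excitation pooled over all three spatial axes. The reference scale
is the B7 compound scaling (width 2.0, depth 3.1), at which the adaptive
average-pooled feature vector has length 2560 — invariant to the spatial
input size by the pooling contract. `width_scale`/`depth_scale` shrink the
network for CPU-scale tests without changing its topology. Training:
cross-entropy over the four grades, Adam at 1e-4, 50 epochs by default,
checkpointing (weights *and* batch-norm running statistics) at the best
macro one-vs-rest validation AUC. No class weighting — balance comes from
augmentation. Batch size defaults to 2 at full resolution (unspecified in
the reference protocol).

Because no deep-learning framework is available in the runtime environment,
both networks run on a bundled numpy layer stack (`renalprog._nn`) with
explicit backward passes, validated against finite-difference gradients in
the test suite. Full-size (B7-scale) training is impractical on CPU and out
of scope; the full-size *forward* pass (feature extraction contract) is
exercised in tests.

## Discrete-time survival model

* **Grid.** `n = 15` equidistant left-closed/right-open intervals; width =
  max duration / n (200 days for a 3000-day horizon). A death exactly at
  the grid maximum is assigned to the last interval rather than dropped.
* **Encoding.** Uncensored: `survs_i = 1` iff `t ≥ t_i`, `survf` marks the
  death interval. Censored: `survs_i = 1` iff `t ≥ (t_{i−1}+t_i)/2`
  (midpoint convention), `survf = 0`. A censoring before the first midpoint
  yields all-zero vectors and contributes zero loss.
* **Network.** input → 32 (ReLU → batch norm → dropout 0.4) → n sigmoid
  outputs interpreted as conditional survival `1 − h_i`. That
  interpretation is pinned by the loss algebra: substituting the indicator
  patterns reproduces `ln(pred)` for survived intervals and `ln(1 − pred)`
  for the death interval, i.e. the classical likelihood with `h = 1 − pred`.
* **Training.** Adam at 1e-3, up to 500 epochs, early stopping with
  patience 10 on the loss of an internal event-stratified validation split
  (20% of the fitting cohort). Full-batch by default (the batch size is a
  free parameter; full batch is deterministic and fastest at these sizes).
  Feature normalization statistics come from the training portion only and
  are stored on the results object for leak-free reuse at prediction time.
  Predictions are clamped to [1e-7, 1 − 1e-7] inside the loss.
* **Curves.** `S(t_j) = ∏_{i≤j} pred_i`, non-increasing by construction;
  continuous curves by linear interpolation through `(0, 1)` and the
  boundary knots — linear-in-S is exactly the constant-density assumption
  within an interval. Default 40 interpolation points; any count ≥ 2
  (e.g. 600 for dense plotting) is available, since the source material is
  ambiguous between the two.

## Evaluation metrics

* **C-index** (Harrell, time-independent): pairs comparable iff the
  strictly shorter observed time had the event; risk ties count 1/2.
  Because a survival *curve* defines no scalar risk, the default risk
  functional is `1 − S(t*)` at the grid's median time; this choice is
  exposed and documented since published C-index values depend on it.
* **IBS**: Graf-style IPCW Brier score with the censoring distribution's
  Kaplan–Meier estimate fitted on the evaluation cohort, on a 100-point
  grid between the minimum and maximum event times, trapezoid-integrated
  and normalized by the span. With no censoring this reduces exactly to the
  mean squared error between curves and survival indicators.
* **Cumulative dynamic AUC**: Uno's IPCW estimator via scikit-survival,
  with its integrated mean AUC.

## Synthetic cohort

The generator emulates the statistical structure of the target cohort, not
its images: 244 patients, grade mix (13.5%, 48.8%, 27.0%, 10.7%), ~32/244
observed deaths, 3000-day horizon, median observation well under the
horizon. Mechanics: death times are geometric-by-interval draws from
grade-specific constant hazards (0.008, 0.015, 0.026, 0.052 per 200-day
interval — synthetic values chosen once so the expected observed death
fraction lands near 32/244 and median survival orders by grade); censoring
is an independent power-function time `C = horizon · U^{θ}` with
`θ = censor_rate/(1 − censor_rate)` (0 → administrative only, 0.5 →
uniform, 1 → immediate). Phantom volumes are ellipsoids with spherical
tumors whose radius, surface bumps and texture variance grow with grade —
sufficient for pipeline and monotonicity testing, with no claim to CT
realism. Feature vectors place grade means `separation` apart along a fixed
low-dimensional direction plus isotropic noise; separation 0 is an exact
null.

A green synthetic test therefore establishes mechanical and statistical
correctness of the pipeline (encodings, likelihood, recovery of known
hazards, metric estimators, fold hygiene) — not clinical performance on
real CT cohorts, which would require the real images and full-scale GPU
training.

## Splitting

Three folds; within each fold the deceased are divided as evenly as
possible (difference ≤ 1) across train/val/test, with overall fractions
33% test / 10% validation / 57% train and the test third rotating so every
patient is tested exactly once. The published description of the split
percentages is internally inconsistent; the implemented rule is the
operational one (even deceased division + stated size fractions). The same
index sets feed both networks, and a leakage assertion (disjointness +
cohort coverage) runs on every plan.

## Desk-scale choices

End-to-end tests and the acceptance script run 36-patient cohorts at 32³
resolution with a width-scale-0.02 backbone, hazards scaled ×4 and
censor_rate 0.3 — the elevated event rate guarantees comparable pairs in
every 12-patient test split. These runs verify determinism and plumbing;
their metric values are not meaningful performance estimates. The
two-group parameter-recovery suite uses 1500 patients so the per-interval
Monte-Carlo error (~0.02 in late intervals) sits well inside its 0.05
acceptance band.

## Known limitations

* No automatic segmentation: kidney/tumor masks are required inputs.
* Full-size grader training on CPU is out of reach; correctness at scale is
  argued via the scale-invariant architecture contracts plus desk-scale
  training behavior.
* The C-index risk functional for curve models is a convention; comparisons
  against published scalar-risk models inherit that choice.
* The midpoint censoring convention discards information from censorings in
  the first half-interval (they contribute zero loss); they are rare on
  sensible grids.
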