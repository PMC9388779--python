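# Methods

`tdcsfc` implements a complete analysis chain for predicting response to
transcranial direct current stimulation (tDCS) in schizophrenia patients with
persistent auditory verbal hallucinations, from baseline resting-state fMRI:
subject-level QC and denoising, left superior temporal gyrus (LSTG)
seed-based functional connectivity, L1-regularized logistic classification
under repeated stratified cross-validation, an optional 3D convolutional
classifier with transfer learning, and exact Shapley attribution aggregated
to atlas regions.  Because no patient data are distributable, the package
ships a synthetic-cohort generator that reproduces the statistical structure
each stage relies on; every empirical claim in this note is computed by the
test suite or the analysis drivers.

## Outcome definition

A patient is a *responder* when the total score on the auditory-hallucination
rating scale (PSYRATS-AH) falls by at least 25% from pre- to post-treatment:

    responder  <=>  100 * (pre - post) / pre >= 25.

The boundary is inclusive.  Pre-treatment scores must be positive.

## Synthetic cohorts

### Geometry

The desk-scale brain is a set of nested ellipsoids on a 24 x 28 x 24 grid at
4 mm isotropic spacing (full scale, 91 x 109 x 91 at 2 mm on the standard
reference grid, is available via `SimConfig.full_scale()` but not required
anywhere).  Semi-axes are fractions of the field of view: brain 0.45, white
matter 0.28, CSF 0.10; gray matter is the brain shell outside the white
matter.  The grid centre sits at (-10, 0, 0) mm so the seed coordinate
(-48, 0, 0) — the LSTG locus — lies inside the gray shell.

The atlas divides gray matter into `n_regions` (default 10) angular sectors:
azimuth wedges crossed with superior/inferior halves, with a seeded rotation
offset.  Sectors of a shell are contiguous by construction, which Voronoi
cells of a non-convex shell are not.  The sector containing the seed voxel
is designated *seed-home*.

### Signal model

Every region carries a latent unit-variance AR(1) series (lag-1 coefficient
0.3, an rs-fMRI-like autocorrelation so that band-pass filtering has a
realistic effect).  Two *discriminative* regions receive

    d = rho * s + sqrt(1 - rho^2) * e,

where `s` is the seed-home latent and `e` an independent AR(1) latent; the
population correlation with the seed is therefore exactly `rho`
(responders: 0.6; non-responders: 0.2 by default — the class contrast the
recovery analyses use).  A voxel's series is its region latent plus white
noise (SD 1.0) plus shared WM/CSF nuisance components mixed in at weight
0.2.  WM and CSF voxels are driven by their own nuisance latents, which is
what gives aCompCor something real to remove.

Spikes add a uniform offset to all in-brain voxels at seeded volumes.  The
amplitude unit is the baseline SD of the scan-to-scan global-signal
difference — the scale the scrubbing z-score is measured on — so an
amplitude-10 spike scores z ~ 10 by construction.  Motion is a small random
walk over six rigid-body parameters; QC-violator subjects get planted
+/-2.5 mm excursions at 40% of volumes.

### Clinical covariates

Covariates are sampled per group from normal distributions with the
reference group means/SDs, truncated to plausible ranges.  The underlying location is
re-centred so the *truncated* mean equals the target mean (naive truncation
would bias, e.g., the responder negative-symptom mean upward by ~1.6
points).  Covariates are sampled independently — no covariance structure is
claimed.  Sex is Bernoulli with the group-specific male fraction (7/17 and
12/17).  Percent improvement is drawn within [25, 95] for responders and
below 25 for non-responders, so the responder rule reproduces the intended
label with zero mismatches (tested).

### What the generator does not emulate

No scanner physics, susceptibility or slice-timing structure, no spatial
autocorrelation beyond region membership, no hemodynamic response shape, no
covariate correlations, and class-homogeneous coupling (every responder has
the same rho).  Classification at desk scale is therefore much easier than
on real data — the recovery analyses validate the *machinery* (leak-free CV,
honest attribution), not clinical effect sizes, and the published accuracies
for real patients are not reproduction targets.

## QC and denoising

* **Scrubbing.**  Volume *t* is censored when the |z| of the scan-to-scan
  global-signal change reaches 9 or composite motion reaches 2 mm.
  Composite motion is the maximum over the six rigid-body parameters of the
  scan-to-scan displacement, rotations converted to arc length on a 50 mm
  sphere (a common convention; no single standard definition exists).
  The difference series is standardized by a two-pass robust mean/SD (points
  beyond 5 robust SDs excluded from the estimate): a naive SD includes the
  spike itself, capping |z| at sqrt((T-1)/2) ~ 8.6 for 150 volumes, which
  would make a threshold of 9 unreachable for any single artifact.
* **Exclusion.**  Subjects failing boundary registration, or with >= 30% of
  volumes censored (inclusive), are dropped, with the reason recorded.
* **aCompCor.**  Top-5 principal component series of the WM and CSF
  compartments (computed on non-censored volumes), the motion series, one
  indicator per censored volume and an intercept are regressed out of every
  voxel.  The indicators absorb censored volumes entirely, so residuals are
  orthogonal (< 1e-8) to every confound on the retained volumes; censored
  volumes are additionally dropped from the later correlation.  Residuals
  are kept in float64 because orthogonality is a 1e-8-level contract.
* **Temporal filtering.**  Per voxel, in order: linear detrend, despike by
  winsorization at 4 SD (the toolbox-specific spline method is not
  specified; winsorization is documented and configurable), then a
  zero-phase frequency-domain band-pass to 0.008-0.09 Hz.  The FFT mask
  preserves pass-band bins exactly and is idempotent in band.
* **Smoothing.**  3D Gaussian at 4 mm FWHM, sigma = FWHM / (2 sqrt(2 ln 2)) /
  voxel size; a FWHM below half a voxel is treated as the identity.

## Seed connectivity and features

The seed ROI is the set of voxels whose centre lies within 15 mm of
(-48, 0, 0) (voxel-centre membership, exactly testable against lattice
enumeration).  The seed-mean series is Pearson-correlated with every voxel
over non-censored volumes (at least 10 required); r is clamped to
+/-(1 - 1e-7) and Fisher-Z transformed (z = arctanh r, so the clamp ceiling
is 8.4056); zero-variance voxels get z = 0 to preserve the fixed-size 3D
matrix the CNN consumes.  Feature vectors concatenate the z-values of the
selected atlas regions in canonical order (label ascending, raster order
within label), independent of the order the regions were requested in; the
voxel->region map is retained for attribution.  The a-priori region list is
configuration data; synthetic runs default to all atlas regions.

## Classification and evaluation

The primary model standardizes features (train-fold mean/SD applied to the
test fold — L1 penalties are scale-sensitive; switchable) and fits
L1-logistic regression at the library-default inverse penalty C = 1.0 with
the liblinear solver.  Evaluation is five shuffled iterations of stratified
10-fold CV: per fold the model trains on 9 folds and predicts the held-out
fold, so no subject contributes to both sides.  Per iteration the confusion
counts over the 10 test folds are pooled (they sum to the cohort size);
accuracy, precision, sensitivity and specificity are reported as mean
(standard error) over the 5 iterations.  Accuracy is primarily the mean of
per-fold accuracies, with the pooled-count variant reported alongside
(`accuracy_pooled`) — the two differ when fold sizes are unequal.  Fold
assignments are recorded so a second model can be evaluated on identical
folds; models are compared by a two-tailed paired t-test on the 50 per-fold
accuracies.  The clinical baseline feeds age, sex, education, untreated and
total illness duration, antipsychotic (olanzapine-equivalent) dose and
baseline symptom scores through the same pipeline, with mean imputation of
missing entries.

Demographic-table utilities: the pooled-variance two-sample t from printed
group summaries, and the Yates continuity-corrected chi-square
(sum (|O - E| - 0.5)^2 / E, correction floored at zero).  Both are
cross-checked against independent library implementations in the tests.

## 3D CNN and transfer learning

The volumetric classifier is a compact, self-contained numpy implementation:
conv blocks (default four, 3^3 kernels, padding 1, 8/16/32/64 filters, each
followed by 2^3 max-pooling with stride 2), flatten, one hidden fully
connected layer with 50% dropout, two logits.  Gradients are analytic per
layer and verified against numerical differentiation.  Training uses
softmax cross-entropy with Adam at learning rate 1e-4, up to 1000 epochs,
with revert-style early stopping: if the best validation error has not
improved by a relative 1e-6 (strict float comparison is seed-fragile) for
100 consecutive epochs, parameters are restored from the checkpoint 100
epochs earlier and training stops.  The checkpoint window holds
patience + 1 states; a scripted-error harness verifies the restored epoch
index exactly.

Pre-training uses a disjoint cohort of 186 healthy controls, 62 unaffected
first-degree relatives, 44 schizophrenia and 149 OCD patients.  Labelling by
clinical global impression: HC/FDR at CGI 0 -> class 0, SZ/OCD at CGI > 3
-> class 1 (441 instances, 248/193); any other record is excluded with a
count.  The minority class is then oversampled within (sex, pooled-age
decile) strata toward the majority's composition until counts are equal
(496 samples); all original records are kept, the majority is untouched,
and empty strata fall back to the nearest age bin.  Oversampling happens
before the train/validation split, which leaks duplicated minority records
across the split — a caveat of the protocol, noted rather than fixed.

Fine-tuning freezes the first `n_frozen_layers` conv blocks (default 4;
"layer" = conv+pool block) and replaces the decision layers with a seeded
re-initialization at 0.1x weight scale, so initial logits are near zero and
early updates refine the transferred features rather than fight random
logits.  Frozen parameters are bit-identical before and after (checksummed).
A known desk-scale limitation: with feature blocks frozen, a head-only
learner can converge *slower* than a fully plastic small CNN, so the
warm-start-advantage test compares pre-trained against random initialization
with all layers trainable, isolating the initialization benefit that
motivates transfer in the first place.

## Attribution

For a linear model with independent features the Shapley value of feature j
for subject i is exactly w_j (x_ij - b_j), with background b the
training-fold feature means (equal to the scaler means, so attributions are
identical in raw or standardized units).  Attributions are computed on each
fold's test subjects and |attribution| averaged over all test predictions
(each subject is tested five times), features ranked descending with ties
broken by canonical index, the top K selected (K = 1000 at full scale; 10%
of features at desk scale), and each region scored by the percentage of
selected voxels it contributes.  Per-subject attributions sum to
margin(x) - margin(background) within 1e-8, and the closed form matches
brute-force coalition enumeration for p <= 10.  Whether ranks should use
signed or absolute values, or train rather than test instances, is
genuinely open; mean |attribution| over test predictions is this package's
documented choice.

## Problem sizes

Tests and drivers run at desk scale: 24 x 28 x 24 x 150 volumes, cohorts of
34-60 subjects, a 16^3 pre-training grid, and two-block CNNs on 8^3 inputs
for the training-loop tests.  The recovery analysis (60 subjects, coupling
contrast 0.4, full QC -> FC -> CV chain) reaches ~85% mean CV accuracy with
the two planted regions as the top two contributions; the label-permuted
null (34 subjects, 500 noise features, 50 permutations) stays within
40-60%.  These sizes were chosen so the whole suite completes in about a
minute while every contract is still exercised end to end.
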