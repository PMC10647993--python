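# Methods

## PRM classification

Each lung voxel is classified from its paired inspiratory/expiratory HU by
two thresholds: −950 HU on inspiration (emphysema cut) and −856 HU on
expiration (air-trapping cut). The implementation uses the half-plane
partition `insp ≤ −950` × `exp ≤ −856`, which is total: every finite HU pair
receives exactly one of the four classes (emphysema, fSAD, normal,
uncategorized). Published prose definitions of the four categories are
mutually inconsistent exactly *on* the thresholds (one category claims
`≤ −950`, another `< −950`); voxels precisely on a threshold are
measure-zero in real data, and this package deterministically assigns them
to the `≤` side.

Volumes are reported in mL (voxel volume from spacing; 1000 mm³ = 1 mL),
percentages relative to the region's lung volume. The 72-parameter vector is
9 quantities (LV, four class volumes, four class percentages) × 8 regions
(whole lung, left lung, right lung, right upper/middle/lower, left
upper/lower), in the fixed order given by `prm.feature_names()`. Lobes 1–3
are the right lung, 4–5 the left. Regions with zero lung volume report 0 for
all percentages and are flagged in `PRMParameterVector.empty_regions` rather
than producing NaNs. Lung voxels not covered by any lobe label are counted
in the whole-lung region only, with a warning.

An optional inspiratory HU validity window (default off) can exclude
airway/vessel-like voxels from the mask before classification; published
pipelines are not explicit about such exclusions, so the default reproduces
the bare threshold rule.

## Registration

The expiratory volume is aligned to the inspiratory grid with
multi-resolution fast-symmetric-forces demons (SimpleITK), 3 levels
(shrink 4/2/1, pre-smoothing 2/1/0 voxels), 120/80/50 iterations, and
displacement-field smoothing sigma 2 voxels. Fields are stored in voxel
units on the fixed grid; resampling is a pull-back `moving[x + d(x)]` with
linear interpolation, and samples falling outside the moving volume are
marked invalid so callers can drop them from the lung mask.

Two numerical choices matter:

* **Intensity handling.** Expiratory lung is denser than inspiratory lung,
  so even perfectly aligned voxels differ in HU. No global monotone
  intensity map exists between the phases, because the shift is
  class-dependent (air-trapping tissue *drops* expiratory density while
  normal tissue raises it); global histogram matching therefore biases the
  match and is not used. Instead the mean HU difference over air-like
  voxels (HU < −400) is subtracted from the expiratory lung, leaving
  non-lung tissue untouched so the high-contrast lung boundary stays
  consistent.
* **Convergence guard.** After estimation the masked mean-squared
  difference of the (offset-corrected) pair is compared against the
  unwarped value; if the warp increased it, the identity field is returned
  and the result flagged non-converged. The guard mask is the lung mask
  proper: a dilated mask is available (`RegistrationSettings.mask_dilation`)
  but defaults to 0, because the ring just outside the lung carries
  resampling artifacts of the correctly discontinuous boundary field and
  contaminates the objective.

On 64³ phantoms warped by a smooth amplitude-2-voxel field, the recovered
field's mean in-mask residual against the generator's stored inverse is
0.3–0.45 voxels across seeds (the stored inverse itself is accurate to
< 1e-3 voxels via fixed-point inversion).

## Staging rules

All comparisons are on fraction-scale spirometry. COPD iff FEV1/FVC < 0.7;
GOLD I/II/III/IV by FEV1% at ≥ 0.80 / ≥ 0.50 / ≥ 0.30 / < 0.30. Non-COPD
subjects are normal iff FEV1% ≥ 0.95, else high-risk. Two gaps in the
published definitions are closed deterministically: FEV1/FVC exactly 0.7 is
non-COPD (consistent with GOLD's strict cut), and non-COPD subjects with
FEV1% below 0.80 — outside the published 0.80–0.95 high-risk band — also
map to high-risk, which is what the published discordant-case table does
with a 0.78 prediction. CSV ingestion auto-detects percent-scaled columns
(median > 2) and rescales, since published tables mix the two scales.

## Regression models

A single scikit-learn estimator, `PFTRegressor`, wraps both families:

* random forest — 500 trees, unlimited depth, `ceil(p/3)` = 26 candidate
  features per split at p = 76, bootstrap on; conventional regression
  defaults, exposed as parameters;
* MLP — hidden layers (64, 32), ReLU, standardized inputs, early stopping
  on 10% of the training data, max 2000 epochs.

Inputs are the 72 PRM parameters plus age, sex (male = 1, female = 0),
height (cm), weight (kg). Predictions are clipped to the physiologic domain
(0, 1.6]. The default split is a seeded 4:1 shuffle (validation =
`round(n/5)`); explicit sizes such as 494/121 are supported because
published splits are not always exactly 4:1. The original study's exact
hyperparameters and split membership are unpublished, so its absolute R²
values are population-dependent and are not targets; the package instead
verifies parameter recovery on synthetic cohorts (below).

## Cascade evaluation

Regression quality: R² (can be negative), MAE, MSE, RMSE, Spearman ρ with
average ranks for ties. R² is reported as not-applicable (NaN, with a
warning) when the true targets have zero variance. Classification from
predicted spirometry proceeds as a cascade mirroring clinical use:

1. COPD vs non-COPD from predicted FEV1/FVC, over the whole validation set;
2. normal vs high-risk from predicted FEV1%, among subjects predicted *and*
   truly non-COPD (truly obstructed subjects have no normal/high-risk
   ground truth);
3. GOLD stage agreement from predicted FEV1%, among truly obstructed
   subjects.

Confusion reports store integer counts; the five metrics are recomputed
properties, with zero-denominator ratios reported as not-applicable (None),
never as 0. Percentages are additionally rounded to integers for
comparability with published reporting style. The discordant-subject list of
task 2 (with each subject's whole-lung fSAD% and emphysema%) equals FP + FN
of that confusion matrix by construction.

## Synthetic phantoms

Lung geometry is five disjoint axis-aligned ellipsoids (three right, two
left) on a ≥ 32³ grid; the lung mask is their union. Each in-mask voxel gets
a PRM class with exact per-lobe counts (largest-remainder rounding of the
configured fractions); voxels are ordered by a smooth random field
(`cluster_scale`, default 4 voxels) so same-class voxels form coherent
patches, as real disease does — `cluster_scale=0` degrades to voxel-wise
salt-and-pepper. HU are sampled uniformly from class-specific intervals
that keep a ≥ 1 HU guard band around the thresholds (inspiration:
emphysema/uncategorized [−1000, −951], fSAD/normal [−949, −700];
expiration: emphysema/fSAD [−1000, −857], normal/uncategorized
[−855, −600]), so a zero-noise, zero-warp phantom classifies back to its
ground truth *exactly*. One spatially smooth quantile field
(`texture_scale`, default 2 voxels) drives both phases, so aligned voxels
are monotonically related in intensity within each class — giving
registration realistic structure to lock onto while each voxel's HU stays
uniform over its interval.

The expiratory warp is a Gaussian-smoothed random vector field
(`warp_smoothness`, default 8 voxels), tapered to zero over 3 voxels at the
lung boundary, scaled to a configured maximum in-lung magnitude
(`warp_amplitude`, voxels). The generator stores both the applied field and
its fixed-point inverse (the field registration should recover). Gaussian
HU noise (`noise_sd`) is added last, independently per phase.

What the phantom does **not** emulate: airways, vessels and fissures; the
global volume change between breath holds (the warp is interior and
zero-mean, not a physiologic deflation); scanner dose/reconstruction
effects; HU distributions beyond uniform-within-interval. Passing phantom
tests therefore demonstrates correctness of the classification, aggregation
and registration machinery under controlled conditions, not clinical-grade
registration accuracy on real anatomy.

## Synthetic cohorts

Per subject, whole-lung disease burden is gamma-distributed (fSAD% shape 2
scale 6, emphysema% shape 1.2 scale 2, uncategorized% shape 1.5 scale 1 —
right-skewed marginals with medians near published cohort medians); per-lobe
burden is the subject level jittered lognormally (log-sd 0.25) and
renormalized, and every regional feature is derived from per-lobe class
*volumes* (total lung volume ~ N(4400, 900) mL truncated, Dirichlet lobe
shares), so volumes and percentages are self-consistent by construction.
Spirometry is linear in the emitted whole-lung percentages:

    FEV1/FVC = 0.88 − 0.006·fSAD% − 0.010·Emph% + ε,  ε ~ N(0, 0.04)
    FEV1%    = 1.13 − 0.012·fSAD% − 0.015·Emph% + ε,  ε ~ N(0, 0.08)

with results clipped to (0, 1.2] and (0, 1.6]. The intercepts and slopes
were chosen once so that rule-based staging of the noiseless spirometry
yields roughly 60% normal / 30% high-risk / 10% COPD, the class balance of
a community screening population; the observed split at n = 5000 is
59/33/8. Group labels are computed from the *noiseless* spirometry, making
the label a deterministic function of the features; the emitted
(measurement-noisy) spirometry is what models regress. Demographics are
independent draws (age ~ N(68, 4) years, P(male) = 0.47, height ~
N(164, 8) cm, weight ~ N(65, 11) kg) and carry no signal — the generative
model runs only through the PRM features, so feature-importance checks have
a known answer.

Because regional variation in real cohorts is unpublished, the lobe-jitter
scale is a free parameter of the generator, not an estimate.

## Verification strategy and problem sizes

The study cohort is unavailable, so verification is (a) exact reproduction
of every derived statistic in the published worked examples (confusion
metrics from printed counts, GOLD accuracy, RMSE from MSE, staging of the
six printed discordant cases), and (b) ground-truth recovery on synthetic
data: exact PRM recovery on a zero-noise 64³ phantom; < 0.5 voxel mean
residual after registering an amplitude-2 warp; held-out R² ≥ 0.95 for the
random forest on a noiseless 500-subject cohort with a 5-permutation
permuted-target mean R² ≤ 0.1. A single permuted fit's R² fluctuates by
~±0.2 across seeds (a handful of extreme-burden subjects dominate the tail
predictions), which is why the null is summarized by its mean. Phantom
sizes of 40³–64³ and cohorts of 500 keep the full suite around a minute
while leaving every per-lobe fraction resolvable to well under one
percentage point.

## Known limitations

* Demons with an offset-corrected MSE force is a pragmatic default; on real
  paired CT with strong air trapping a mutual-information or
  local-correlation metric is preferable (supported conceptually via
  `apply_precomputed_alignment`, which accepts externally computed fields).
* The staging high-risk band follows one published screening definition;
  symptom- and smoking-based risk definitions are out of scope.
* No DICOM ingestion (NIfTI only); no lobe segmentation — lobe masks are an
  input.
* The MLP is a reproducible baseline, not a tuned competitor; on small
  synthetic cohorts it is expected to trail the random forest, and does.
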