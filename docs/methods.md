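# Methods

This note documents the models, conventions and numerical choices behind
`dpdquant`: the marker definitions, the geometric primitives they rest on,
the digital phantom used for verification, and the cohort statistics.

## Geometry and units

All physical reasoning happens in world millimetres. A `GridGeometry`
carries voxel counts, per-axis spacing (mm), the world position of the first
voxel *center*, and an orthonormal direction matrix (NIfTI direction-cosine
semantics). World coordinates always refer to voxel centers; voxel volume is
the product of spacings / 1000 (mL). CT and SPECT are assumed coregistered
into one world frame, as guaranteed by a hybrid scanner; no registration is
performed, and misaligned inputs are the caller's responsibility.

SUV conversion divides activity concentration (Bq/mL) by injected activity
per gram of body weight, with the activity decayed to **acquisition start**
(half-life default 6.0067 h for Tc-99m). Whether the decay reference should
be injection or acquisition time is a convention choice; both Δt and the
half-life are exposed, and the acquisition-start convention is what the
package implements.

### Mask transfer and expansion

* `resample_mask` is nearest-neighbor in world coordinates: a target voxel
  takes the value of the source voxel whose center is nearest to the target
  center, with background outside the source grid (the standard NN
  convention; pure nearest-center semantics would extrapolate masks
  arbitrarily far). Nearest-neighbor was chosen over linear-then-threshold
  because it preserves binarity and admits an exact brute-force oracle.
* `dilate_mm` thresholds an exact anisotropic Euclidean distance transform:
  an output voxel is set iff some input voxel center lies within the radius
  (voxel-center-to-voxel-center distance). This makes the 10 mm expansion
  reproducible and oracle-checkable; there is no sub-voxel surface model.
  A 1e-9 mm tolerance keeps exactly-on-boundary centers stable under
  floating-point square roots.

### Order of transfer and expansion

Masks are delineated on the CT grid but quantified on the SPECT grid. The
package resamples the *undilated* mask to the SPECT grid and dilates there.
Dilating on CT first and then transferring is the other defensible order;
because the dilation radius is physical (mm) and the grids share a world
frame, the two differ only by single-voxel partial-volume effects at the
region boundary. One order had to be fixed for determinism; resample-first
keeps each marker function self-contained on the SPECT grid.

## Marker definitions

With `ExtractionConfig` defaults (expansion 10 mm, VOI 1 mL, TBR threshold
1, retention-index masks undilated):

* **SUVmax / SUVmean** — max / arithmetic mean over the 10-mm-expanded
  structure mask.
* **SUVpeak** — sphere of volume 1 mL (r = (3V/4π)^⅓ ≈ 6.2035 mm);
  candidate centers are the in-mask voxel centers; sphere membership is
  voxel-center-within-radius with no partial-volume weighting; the sphere
  may extend beyond the mask but is clipped at image bounds (the mean is
  over in-bounds members). The returned value is the max of the sphere mean
  over candidate centers; ties are irrelevant to the value, and the logged
  argmax is the first in lexicographic index order. Implemented as one
  convolution of values and of an indicator (sum / count), shared across
  structures in `extract_panel`. If the grid is so coarse that the sphere
  holds only the center voxel and the voxel is larger than the VOI, a
  degenerate-geometry error is raised rather than returning SUVmax.
* **Retention index** — SUVpeak(myocardium) / SUVpeak(T9) ×
  SUVpeak(paraspinal), the paraspinal mask first cropped axially to the
  world-z interval spanned by the T7–T11 vertebra voxel centers ("between
  T7 and T11" read as an axial clause). Masks are *not* 10-mm expanded by
  default — the expansion sentence targets the per-structure SUV metrics;
  a config flag (`dilate_for_retention_index`) enables the alternative
  reading.
* **Amyloid activity** — SUVmean over the expanded region × region volume;
  algebraically the voxelwise SUV sum over the region × voxel volume.
* **Affected volume** — the SPECT volume is divided by the arithmetic mean
  SUV over the raw (undilated) IVC mask; "thresholded for values below 1"
  is read as *discarding* sub-threshold voxels, so affected = TBR ≥ 1
  (inclusive boundary: "affected" means uptake at or above the blood-pool
  background, and inclusivity makes the saturated case exact). Both the
  threshold direction and the raw-IVC reference are config-visible choices.
* **Panel composition** — exactly 26 markers: {SUVmax, SUVmean, SUVpeak} ×
  5 structures, retention index, amyloid activity × 5, affected volume × 5.
  Combined-ventricles / combined-atria SUV metrics exist behind
  `include_combined_chambers` (off by default) and are reported as extras,
  outside the 26-entry panel. Myocardium and LV overlap anatomically and
  are quantified independently; no mutual exclusion is applied.

Useful invariants, asserted in the test suite: scaling the SUV volume by
c > 0 scales every SUV metric, amyloid activity and the retention index by
c (the RI ratio cancels one factor; the muscle term contributes one), while
affected volume is invariant (TBR cancels the scale); SUVmean ≤ SUVpeak ≤
SUVmax whenever the region contains a full sphere.

## Digital thorax phantom

`default_thorax()` builds a 240 × 240 × 288 mm field of view (3 mm voxels
by default): an ellipsoidal-shell myocardium (inner radii 26/26/34 mm,
wall 14 mm) around an LV chamber ellipsoid, RV/LA/RA ellipsoids, five
vertebral cylinders (radius 13 mm, height 20 mm, 25 mm pitch), a right
paraspinal box spanning the T7–T11 range, and an IVC cylinder. Rasterization
is voxel-center-inside-surface, so analytic volumes are countable exactly.
Default uptakes model a strongly tracer-avid amyloid heart: myocardium SUV
12, blood-pool chambers 1.6–2.0, vertebrae 5, paraspinal and IVC 1,
background 0.5 — giving a retention index of 12/5 × 1 = 2.4 and marker
magnitudes in the range reported for Perugini-grade ≥ 2 patients.

The emitted masks are the **pre-blur** rasterizations (the "CT truth"),
while the emission image is degraded by a Gaussian PSF (default 8 mm FWHM,
a typical reconstructed SPECT resolution) and optional Gaussian or scaled
Poisson noise — deliberately reproducing the spill-out situation the 10 mm
expansion addresses. Negative values after Gaussian noise are clipped to 0
(SUV is non-negative); at the default noise scales the induced bias is
negligible except in air. Ground truth is computed from the clean image
with direct element-wise code (explicit sphere enumeration for SUVpeak),
sharing only `dilate_mm` with the extraction path; on an unblurred,
noiseless phantom the extracted panel equals the truth to floating-point
precision. Determinism: one root seed; cohort patients draw from
`SeedSequence.spawn` streams, so results do not depend on generation order.

What the phantom does *not* model: projection-domain physics (collimator
response, attenuation, scatter, reconstruction artifacts), cardiac/
respiratory motion, anatomical variability, and segmentation error (masks
are exact by construction). Passing tests therefore validate the marker
*definitions* and their implementation, not robustness to real acquisition
physics.

Blur-recovery tolerance: for the 8 mm FWHM test we pre-registered 15%
relative error on the myocardial core SUVmean (mask eroded 5 mm from both
surfaces). A 1-D slab bound gives recovery ≥ Φ(5/σ) + Φ(9/σ) − 1 ≈ 0.92 of
truth at σ = 3.4 mm for a 14 mm wall, before curvature and discretization.

## Cohort simulator

`generate_cohort` draws per-marker baselines from log-normals whose medians
and IQRs match the published 45-patient cohort table (stored in
`dpdquant.reference` as input data); post-treatment values apply per-marker
multiplicative effects (default: the published post/pre median ratios) with
patient-level log-normal noise (SD 0.10). Covariates (age 77 ± 10, 82%
male, treatment 37/5/3 tafamidis/patisiran/inotersen, NYHA and functional
parameters) follow the published cohort distributions. Event times are
exponential with baseline hazard 0.016/month, multiplied by a configurable
hazard ratio (default 3.19) when the right-ventricular affected-volume
change is ≥ 0; censoring is uniform over 12–72 months. These constants give
roughly half the cohort an event over a ~45-month median follow-up,
matching the reported outcome burden; they were fixed once at design time.

## Statistics

* Normality gating uses Shapiro–Wilk at α = 0.05 on the *paired
  differences* (paired tests) or *per group* (two-sample tests); the gate's
  operand is a convention choice documented here. Samples of < 3 or with
  zero range take the non-parametric path.
* Wilcoxon signed-rank drops zero differences (classical convention), uses
  the exact null for small samples without ties and the
  continuity-corrected normal approximation otherwise (scipy's `auto`).
  An all-zero difference vector returns p = 1 with a degenerate flag.
* Categorical comparisons use Fisher's exact test for 2×2 tables with any
  expected count < 5, chi-square otherwise.
* Survival: strata are Δ ≥ 0 ("not reduced") vs Δ < 0; Δ = 0 goes to the
  not-reduced stratum. Kaplan–Meier, log-rank and Cox models come from
  lifelines. The adjusted model uses age, sex (male = 1), treatment
  dummy-coded with tafamidis as reference, and changes in troponin T,
  NT-proBNP, 6MWD and NYHA class; continuous covariates are z-scaled for
  conditioning (the reported hazard ratio is for the change-direction
  indicator and is invariant to covariate scaling). Missing covariates are
  handled complete-case with counts reported.
* ICC is ICC(2,1) — two-way random effects, absolute agreement, single
  rater — computed from the classical variance components; this is the
  conservative standard when readers are interchangeable. Identical
  readers give ICC exactly 1 (0/0 resolved by the limit); zero
  between-subject variance raises a degenerate-variance error.
* No multiple-testing correction is applied anywhere; outputs label p
  values as unadjusted. The marker change table is sorted by ascending p
  (most significant first), ties broken by marker name.

## Problem sizes and limitations

The verification suite uses the default 80×80×96 phantom (≈ 0.6 M voxels),
100 random ≤ 13³ instances for the dilation and SUVpeak brute-force
oracles, 1000 simulated null cohorts of n = 45 for type-I calibration, and
20 replicate n = 200 cohorts for hazard-ratio recovery — sizes at which the
Monte-Carlo error of each check is small relative to its acceptance band.

Known limitations: no DICOM ingestion (NIfTI-1 only); exact coregistration
is assumed; the SUVpeak sphere has no partial-volume weighting, so values
on coarse grids depend on voxel phase; the phantom's analytic shapes are
idealized; and the cohort simulator's covariates are drawn independently
(no realistic correlation structure between markers and clinical course
beyond the programmed hazard link).
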