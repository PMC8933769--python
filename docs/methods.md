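# Methods

This note documents the models and procedures implemented in `amypet`,
the parameter defaults and why they were chosen, what the synthetic
fixtures do and do not emulate, and the numerical decisions that were
genuinely open.

## Coordinate conventions and the analysis grid

All images are carried as (`data`, `affine`) pairs: a 3-D scalar array
plus a 4×4 voxel-index→world-mm map in the RAS+ convention with 0-based
indices. The default analysis grid is the common 2 mm isotropic MNI152
box, 91 × 109 × 91 voxels, whose voxel (45, 63, 36) sits at the world
origin. One voxel is 8 mm³, so the 300-voxel cluster-extent threshold
corresponds to 2.4 cc.

NaN or Inf voxels in input files are a hard error, never silently
zeroed: a zeroed NaN inside a reference VOI would silently bias every
SUVR derived from it.

## Centiloid pipeline

The SUVR is the unweighted mean of the standardized PET over the global
cortical + striatal target VOI divided by its mean over one of four
reference VOIs. The Centiloid conversion is linear per (tracer,
reference) pair; the coefficients ship as a versioned CSV
(`amypet/data/calibration.csv`) rather than constants in code, so new
tracers or revised calibrations can be added without touching logic. The
14 published pairs are present; requesting any of the six pairs without
a published conversion (florbetapir or flutemetamol against cerebellar
gray, whole cerebellum + brainstem, or pons) raises
`NoConversionError` rather than guessing.

CL values are stored unrounded; individual subjects may legitimately
fall outside [0, 100] (the scale's anchors are cohort means, not
bounds).

Validation regression (`validate_against_reference`) follows the
replication convention for published CL values: ordinary least squares
of *computed on reference* (computed = a + b·reference), with R² the
squared Pearson correlation, and pass bands slope ∈ [0.98, 1.02],
|intercept| ≤ 2 CL, R² > 0.98. The axis order is deliberate and
documented so users do not flip it.

## Registration

`register_linear` maximizes Studholme normalized mutual information,
NMI = (H(fixed) + H(moving)) / H(fixed, moving), over a 64 × 64 joint
histogram spanning each image's 1st–99th intensity percentiles.
The search is derivative-free Powell in physical parameters
(translations in mm, Euler rotations in degrees, scales/shears in
percent — all O(1) so the default direction set is well-conditioned),
rotating about the fixed image's world center. Two resolution levels
are used: an anti-aliased ~4 mm level searched from multiple seeded
starts (3 by default, seed 0), then an iteration-bounded warm-started
refinement at native resolution. The fixed image is cropped to the
bounding box of its above-median content (plus 12 mm margin) so the
joint histogram is not dominated by empty background. Registration is
deterministic for a fixed seed; an unconverged coarse search is
reported via a warning and the `converged` flag, with the best
transform still returned.

On noiseless blurred phantoms, random rigid displacements up to 10 mm /
10° are recovered to ~0.02 mm and ~0.05°, comfortably inside the
0.5 mm / 0.5° acceptance band; a 5 % affine scale is recovered within
1 %. The recovery experiment uses 64³ phantoms at 3 mm
(`amypet.evaluation.registration_recovery_experiment`), a size chosen
to keep each case around ten seconds; accuracy is resolution-limited
only weakly since the optimum is interpolated sub-voxel.

Nonlinear spatial normalization is *not* re-implemented. The pipeline
consumes externally computed deformation fields (5-D NIfTI displacement
volumes in mm, applied by pull-back sampling), or falls back to
12-parameter affine normalization against a user-supplied template.
Segmentation-based warping is a research field of its own and is
treated as an imported step.

## Z-score mapping

Processing order for both database controls and subjects: Gaussian
smoothing (default 8 mm FWHM, σ = FWHM/(2√(2 ln 2)) per axis expressed
in voxels), then division by the reference-VOI mean, then masking at
statistics time (data are never zeroed in place). The analysis mask is
the global target VOI minus an optional white-matter mask — white
matter carries high nonspecific uptake in amyloid PET. How that WM mask
is derived is a user contract (any binary mask on the grid, e.g. a
thresholded tissue-probability map); the synthetic fixture ships its
own.

The normative database is the voxelwise mean and *sample* SD (n − 1
denominator) over controls whose global CL is below 10 — the level
reported to exclude subjects with neuritic plaques. The denominator
choice is material at realistic database sizes (n = 10–34) and is
recorded in the database metadata. Controls failing the CL filter are
excluded and logged, never silently used.

Subject/database consistency is enforced through provenance tags
(`fwhm_mm`, `reference`) carried on the volume: a subject smoothed or
normalized differently from the database is an error, not a warning.
Voxels whose control SD is below 10⁻⁶ × (mean SD over the mask) — with
an absolute floor of 10⁻¹² — are removed from the mask and counted in
the Z-map report; clamping them would manufacture arbitrarily large
fake Z values.

Clusters are connected components of {Z ≥ threshold} (default 2.6,
one-sided p < 0.01) under 18-connectivity by default (a common choice
for 3-D statistical maps; configurable to 6 or 26), kept if at least
300 voxels. Testing is one-sided positive only: amyloid accumulation is
an increase, so negative Z is rendered but never drives a call. A
reporting region is positive when ≥ 1 voxel of ≥ 1 surviving cluster
lies inside it; overlap counts are reported so borderline single-voxel
overlaps are visible to the user.

## Between-tracer agreement and CL cutoffs

`chi_square_2x2` is the plain Pearson statistic Σ(O−E)²/E on a 2×2
table with p from the χ²(1) upper tail, *without* Yates continuity
correction — the uncorrected statistic is what published agreement
tables of this kind report, and the package reproduces them to the
third decimal. Degenerate margins yield statistic 0 with a flag.

`roc_analysis` sweeps thresholds over midpoints of sorted unique scores
(plus ±∞), calling positive at score ≥ threshold. AUC is the
trapezoidal area, identical to the Mann–Whitney concordance with ties
counted ½ (cross-checked against a brute-force pairwise oracle in the
tests). The operating cutoff maximizes accuracy (TP + TN)/N — matching
the "most accurate detection" framing used for published CL cutoffs —
with ties broken toward the lowest cutoff; Youden's J is available as
an option.

## Synthetic data: what it emulates and what it does not

Phantoms are *geometric*, not anatomical: an ellipsoidal cerebrum with
a cortical shell split into five disjoint sectors, central striatal
blobs, a deep white-matter core, and separate cerebellum/pons
ellipsoids for the reference regions. Geometry is defined in
grid-fraction coordinates, and proportions are set so that every
reference mask has ≥ 500 voxels and every reporting region ≥ 400 voxels
even on the smallest admissible grid (40 voxels per axis) — which makes
the pons and striatum generously sized relative to anatomy. This is
deliberate: the quantification mathematics (VOI means, ratios, Z
statistics, cluster extents) is geometry-agnostic, and geometric
phantoms give exact ground truth without shipping template images.

Uptake is piecewise-constant per compartment; ground-truth SUVR is the
mask mean of the pre-blur, pre-noise volume (exact for any uptake
configuration) and ground-truth CL follows from the shipped
calibration. An optional Gaussian PSF blur emulates scanner resolution;
noise is additive Gaussian on counts with SD relative to background
(default 0.25 in cohort draws), added post-blur. This is a statistics
testbed, **not** a PET physics model: no attenuation, scatter, randoms,
reconstruction artifacts, or anatomical variability. Passing tests
demonstrate the correctness of the pipeline's mathematics and its
operating characteristics under the stated noise model — not clinical
performance on real scans.

Cohort draws jitter each compartment's uptake multiplicatively
(between-subject SD 0.005) and add voxel noise (SD 0.25 of background,
suppressed roughly 15-fold by the 8 mm pipeline smoothing). The control
template sits at SUVR ≈ 1.05 (CL ≈ 4 for PiB/WhlCbl), i.e. clearly
amyloid-negative; white matter at 1.8× background. With these defaults
the post-pipeline control SD is ≈ 0.02 in normalized units, dominated
by smoothed voxel noise with a ~3.4 mm correlation length — so null
subjects produce scattered, small suprathreshold islands (mean
suprathreshold fraction < 1 %, any-region false-positive rate 1–2 %)
rather than region-sized excursions.

Patient lesions are compact blobs of region voxels nearest the region
centroid. The requested effect size is in *control-SD units on the
processed scale*: the raw amplitude is effect × (median control SD over
the lesion) × (reference level), divided by the median smoothing
attenuation of the lesion's indicator function (≈ 0.7 for a 600-voxel
cortical blob at 8 mm FWHM). Without that compensation a nominal 5-SD
lesion would arrive at ≈ 3.5 SD after smoothing and detection would be
threshold-marginal; with it, a 5-SD 600-voxel lesion is detected in
100/100 simulations across seeds as exactly one surviving cluster in
the correct region.

## Experiment sizes

The standing validation experiments (`amypet.evaluation`) use: 20
noiseless phantoms for the CL regression (which is exact by
construction — slope 1, intercept 0, R² = 1 — since no noise or blur
intervenes between ground truth and measurement); 30 controls and
2 × 100 simulated subjects for the Z-map operating characteristics on
the full 2 mm grid; and 3 random rigid cases at 64³ × 3 mm for
registration recovery. These sizes were chosen as the smallest that
exercise each claim with clear margins.

## Known limitations

* No DICOM ingestion, 4-D dynamic PET, or partial-volume correction.
* Nonlinear warping quality is inherited entirely from the external
  tool that produced the deformation field; the built-in affine
  fallback is coarser than unified segmentation.
* The white-matter masking rule is a user contract, not derived
  in-package.
* The ROC cutoff is reported without confidence intervals, and the χ²
  comparison treats paired tracer data as unpaired (matching the
  published analyses it reproduces; McNemar's test would be the paired
  alternative).
* Rendering is limited to orthogonal slice PNG overlays; no surface
  rendering.
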