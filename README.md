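# amypet

Quantification of amyloid PET scans: the global **Centiloid (CL) scale**
for the five amyloid tracers in clinical use, and **voxelwise Z-score
mapping** of local amyloid accumulation against a normative database of
amyloid-negative controls.

Amyloid PET is usually read visually, which leaves equivocal scans to
inter-rater judgment. This package implements the two quantitative
analyses a clinic or research group needs on top of a standard spatial
normalization:

1. **Centiloid pipeline** — from a spatially standardized PET volume,
   compute the standardized uptake value ratio

   ```
   SUVR = mean(PET | target VOI) / mean(PET | reference VOI)
   ```

   over a global cortical + striatal target and one of four reference
   regions (whole cerebellum `WhlCbl`, cerebellar gray `CerebGry`, pons
   `Pons`, whole cerebellum + brainstem `WhlCblBrnStm`), then map it to
   the common 0–100 Centiloid scale with the published tracer-specific
   linear calibration, `CL = intercept + slope × SUVR`. The shipped
   calibration table covers all 14 published (tracer, reference) pairs
   for ¹¹C-PiB, ¹⁸F-florbetapir, ¹⁸F-flutemetamol, ¹⁸F-florbetaben and
   ¹⁸F-NAV4694; the six unpublished pairs raise an explicit
   "no published conversion" error.

2. **Z-score mapping** — smooth the standardized PET (8 mm FWHM),
   normalize it by the reference-VOI mean, and compare voxelwise with
   the mean/SD images of a control database built identically from
   young healthy controls with CL < 10:

   ```
   Z(v) = (subject(v) − mean_controls(v)) / sd_controls(v)
   ```

   Voxels with Z ≥ 2.6 (one-sided p < 0.01) forming connected clusters
   of ≥ 300 voxels (2.4 cc on the 2 mm grid) count as significant;
   five reporting regions (posterior cingulate + precuneus, frontal,
   temporal, parietal cortex, striatum) are called positive when a
   surviving cluster touches them.

Rigid/affine registration to template space (normalized mutual
information, Powell search) and application of externally computed
nonlinear deformation fields are included; tissue-segmentation-based
warping itself is delegated to external tools (e.g. SPM), whose
deformation fields can be supplied as NIfTI displacement volumes.

A synthetic-data module generates geometric brain phantoms, VOI sets,
control cohorts and lesioned patients with exact ground truth, so the
entire pipeline is testable without any image downloads.

## Worked example

Generate a synthetic cohort (12 controls, one patient with a 5-SD,
600-voxel lesion in the posterior cingulate/precuneus), build the
normative database, and run both analyses:

```bash
amypet simulate --n-controls 12 --n-patients 1 \
    --effect pcc_precuneus=5 --seed 7 --out demo/bundle
amypet build-db --controls-csv demo/bundle/controls/controls.csv \
    --voi-dir demo/bundle/vois --wm-mask demo/bundle/vois/wm_mask.nii.gz \
    --tracer pib --reference whlcbl --out demo/db
amypet centiloid --pet demo/bundle/patients/patient_000.nii.gz \
    --voi-dir demo/bundle/vois --skip-registration \
    --tracer pib --reference whlcbl --out demo/cl
amypet zmap --pet demo/bundle/patients/patient_000.nii.gz \
    --db demo/db --voi-dir demo/bundle/vois --skip-registration --out demo/z
```

`demo/cl/suvr_cl.json` then contains (abridged):

```json
{"target_mean": 1.0546, "reference_mean": 0.9574,
 "suvr": 1.1015, "cl": 8.63}
```

— a target/reference count ratio of 1.10, i.e. CL ≈ 8.6: the focal
lesion barely moves the *global* burden of an otherwise
amyloid-negative subject (young controls sit near CL 0, typical AD near
CL 100). The Z-map, however, localizes it. `demo/z/clusters.json`
reports one surviving cluster (924 voxels, peak Z = 12.6) and
`demo/z/regional_calls.json`:

```json
{"pcc_precuneus": {"call": "positive", "overlap_voxels": 906},
 "parietal":      {"call": "positive", "overlap_voxels": 18},
 "frontal":   {"call": "negative"}, "temporal": {"call": "negative"},
 "striatum":  {"call": "negative"}}
```

The injected region is positive; the 18-voxel parietal overlap is the
smoothed lesion spilling across the adjacent region boundary. Slice
overlays with the target-region contour are written under
`demo/z/slices/`.

Every output JSON embeds the fully resolved run configuration and the
package version.

## Library layout

| module | contents |
|---|---|
| `amypet.volumes` | `Volume`/`Mask`/`Grid3D`, NIfTI I/O, resampling, Gaussian smoothing, origin setting |
| `amypet.registration` | NMI rigid/affine registration, deformation-field application |
| `amypet.voi` | VOI set loading/validation, mask means, partition report |
| `amypet.centiloid` | SUVR, SUVR→CL calibration table, Klunk-style validation regression |
| `amypet.zmap` | normative database, Z-maps, cluster-extent thresholding, regional calls, overlays |
| `amypet.stats` | Pearson χ² (2×2), ROC with max-accuracy CL cutoff |
| `amypet.synthetic` | phantoms, VOI sets, cohort generators with ground truth |
| `amypet.evaluation` | end-to-end validation experiments |
| `amypet.cli` | `amypet` command-line interface |

See `docs/methods.md` for the underlying models, parameter defaults and
limitations.
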