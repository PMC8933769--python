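"""Z-score mapping against a normative database of amyloid-negative controls.

The statistical comparison pipeline: the spatially standardized subject
PET is smoothed (default 8 mm FWHM), normalized by its reference-VOI
mean, and compared voxelwise with the mean and standard deviation images
of a control database built the same way from young healthy controls
whose global amyloid burden is below a Centiloid threshold (default
CL < 10, the level reported to exclude neuritic plaques):

    Z = (subject - control mean) / control SD.

Voxels outside the analysis mask (global target minus an optional
white-matter mask) carry no Z value. Significant accumulation is
declared where Z exceeds a threshold (default 2.6, one-sided p < 0.01)
in a connected cluster of at least a minimum extent (default 300 voxels
= 2.4 cc on the 2 mm grid); a reporting region is called positive when
any surviving cluster touches it. Testing is one-sided in the positive
direction only — amyloid accumulation is an increase.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .voi import REGION_NAMES, VOISet, mask_mean
from .volumes import Mask, Volume, gaussian_smooth, read_mask, read_volume, \
    write_mask, write_volume

__all__ = [
    "NormativeDB",
    "ZMap",
    "Cluster",
    "ClusterSet",
    "RegionalCalls",
    "normalize_by_reference",
    "build_analysis_mask",
    "build_normative_db",
    "compute_zmap",
    "threshold_clusters",
    "regional_positivity",
    "render_overlay",
    "save_normative_db",
    "load_normative_db",
]

logger = logging.getLogger(__name__)


def normalize_by_reference(pet_std: Volume, vs: VOISet, reference: str) -> Volume:
    """Divide every voxel by the reference-VOI mean.

    The output's reference mean is exactly 1, which makes the operation
    idempotent and cancels any global intensity scale of the scanner.
    The reference name is recorded in ``meta['reference']``.
    """
    from .centiloid import canonical_reference

    reference = canonical_reference(reference)
    ref_mean = mask_mean(pet_std, vs.reference_masks[reference])
    if ref_mean <= 0:
        raise ValueError(
            f"non-positive reference mean ({ref_mean:g}) in {reference!r}"
        )
    return pet_std.with_data(pet_std.data / ref_mean, reference=reference)


def build_analysis_mask(vs: VOISet, wm_mask: Mask | None = None) -> Mask:
    """Analysis mask = global target VOI minus the white-matter mask.

    White matter carries high nonspecific counts in amyloid PET; removing
    it keeps the Z statistics to gray-matter target tissue. With no WM
    mask the target VOI is used unchanged.
    """
    if wm_mask is None:
        return Mask(grid=vs.grid, data=vs.target_mask.data.copy(),
                    name="analysis")
    if not wm_mask.grid.matches(vs.grid):
        raise ValueError("white-matter mask grid does not match VOI grid")
    data = vs.target_mask.data & ~wm_mask.data
    if not data.any():
        raise ValueError("empty analysis mask: white-matter mask covers the target")
    return Mask(grid=vs.grid, data=data, name="analysis")


@dataclass
class NormativeDB:
    """Voxelwise mean/SD images of processed amyloid-negative controls."""

    tracer: str
    reference: str
    mean_volume: Volume
    sd_volume: Volume
    n_controls: int
    analysis_mask: Mask
    cl_threshold: float = 10.0
    fwhm_mm: float = 8.0
    excluded: list[dict] = field(default_factory=list)
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("normative database needs >= 2 controls")
        if not self.mean_volume.grid.matches(self.sd_volume.grid):
            raise ValueError("mean and SD volumes are on different grids")
        if np.any(self.sd_volume.data < 0):
            raise ValueError("negative SD voxels")


@dataclass
class ZMap:
    z: Volume
    db: NormativeDB
    n_sd_excluded: int = 0  # near-zero-variance voxels dropped from the mask
    mask: Mask | None = None

    @property
    def analysis_mask(self) -> Mask:
        return self.mask if self.mask is not None else self.db.analysis_mask


def _process_control(
    pet_std: Volume, vs: VOISet, reference: str, fwhm_mm: float
) -> Volume:
    sm = gaussian_smooth(pet_std, fwhm_mm)
    return normalize_by_reference(sm, vs, reference)


def build_normative_db(
    controls: list[tuple[Volume, float]],
    vs: VOISet,
    tracer: str,
    reference: str,
    fwhm_mm: float = 8.0,
    cl_threshold: float = 10.0,
    wm_mask: Mask | None = None,
) -> NormativeDB:
    """Build the control database from (standardized PET, global CL) pairs.

    Controls at or above the CL threshold are excluded (and logged):
    an amyloid-positive "control" would inflate the mean and SD and hide
    true accumulation. Each survivor is smoothed then
    reference-normalized; the voxelwise mean and *sample* SD (n-1
    denominator — material at the typical database sizes of 10-34) form
    the database.
    """
    from .centiloid import canonical_tracer, canonical_reference

    tracer = canonical_tracer(tracer)
    reference = canonical_reference(reference)
    survivors, excluded = [], []
    for i, (vol, cl) in enumerate(controls):
        if cl < cl_threshold:
            survivors.append(vol)
        else:
            excluded.append({"index": i, "cl": float(cl)})
            logger.info("excluding control %d with CL %.2f >= %.2f",
                        i, cl, cl_threshold)
    if len(survivors) < 2:
        raise ValueError(
            f"only {len(survivors)} controls below CL {cl_threshold}; need >= 2"
        )
    stack = np.stack(
        [_process_control(v, vs, reference, fwhm_mm).data for v in survivors]
    )
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    grid = vs.grid
    return NormativeDB(
        tracer=tracer,
        reference=reference,
        mean_volume=Volume(grid=grid, data=mean,
                           meta={"fwhm_mm": fwhm_mm, "reference": reference}),
        sd_volume=Volume(grid=grid, data=sd,
                         meta={"fwhm_mm": fwhm_mm, "reference": reference}),
        n_controls=len(survivors),
        analysis_mask=build_analysis_mask(vs, wm_mask),
        cl_threshold=cl_threshold,
        fwhm_mm=fwhm_mm,
        excluded=excluded,
    )


def prepare_subject(
    pet_std: Volume, vs: VOISet, db: NormativeDB
) -> Volume:
    """Smooth and normalize a standardized subject PET exactly as the
    database controls were processed."""
    return _process_control(pet_std, vs, db.reference, db.fwhm_mm)


def compute_zmap(
    subject_norm: Volume, db: NormativeDB, sd_floor_rel: float = 1e-6
) -> ZMap:
    """Voxelwise Z = (subject - mean) / SD inside the analysis mask.

    The subject must have been smoothed and reference-normalized exactly
    like the database controls; this is verified through the volume's
    provenance tags and a mismatch is an error, not a warning. Voxels
    whose SD is below ``sd_floor_rel`` times the mask-mean SD are removed
    from the mask and counted — clamping them would manufacture huge fake
    Z values.
    """
    if not subject_norm.grid.matches(db.mean_volume.grid):
        raise ValueError("subject grid does not match database grid")
    fwhm = subject_norm.meta.get("fwhm_mm")
    if fwhm is None or abs(float(fwhm) - db.fwhm_mm) > 1e-6:
        raise ValueError(
            f"provenance mismatch: subject smoothed at {fwhm} mm FWHM, "
            f"database at {db.fwhm_mm} mm"
        )
    ref = subject_norm.meta.get("reference")
    if ref != db.reference:
        raise ValueError(
            f"provenance mismatch: subject normalized by {ref!r}, "
            f"database by {db.reference!r}"
        )
    mask = db.analysis_mask.data.copy()
    sd = db.sd_volume.data
    eps = max(sd_floor_rel * float(sd[mask].mean()), 1e-12)
    low_sd = mask & (sd < eps)
    n_excl = int(low_sd.sum())
    mask &= ~low_sd
    z = np.zeros(subject_norm.grid.dims)
    z[mask] = (subject_norm.data[mask] - db.mean_volume.data[mask]) / sd[mask]
    zvol = Volume(grid=subject_norm.grid, data=z,
                  meta={"kind": "zmap", "tracer": db.tracer,
                        "reference": db.reference})
    return ZMap(z=zvol, db=db, n_sd_excluded=n_excl,
                mask=Mask(grid=subject_norm.grid, data=mask, name="analysis"))


@dataclass(frozen=True)
class Cluster:
    voxels: np.ndarray     # (k, 3) integer indices
    size: int
    peak_z: float
    centroid_mm: tuple[float, float, float]


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    z_threshold: float
    min_voxels: int
    connectivity: int

    def __len__(self) -> int:
        return len(self.clusters)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def threshold_clusters(
    zm: ZMap,
    z_threshold: float = 2.6,
    min_voxels: int = 300,
    connectivity: int = 18,
) -> ClusterSet:
    """Suprathreshold connected components with a cluster-extent filter.

    Components of {Z >= z_threshold} under 6/18/26-connectivity smaller
    than ``min_voxels`` are discarded (the joint Z/extent rule controls
    false positives in lieu of voxelwise multiple-comparison correction).
    Survivors are sorted by size, then peak Z, then centroid.
    """
    if z_threshold <= 0 or min_voxels <= 0:
        raise ValueError("z_threshold and min_voxels must be positive")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    supra = zm.z.data >= z_threshold
    supra &= zm.analysis_mask.data
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(supra, structure=structure)
    clusters = []
    if n:
        sizes = ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1))
        aff = zm.z.grid.affine
        for lab, size in zip(range(1, n + 1), sizes):
            if size < min_voxels:
                continue
            vox = np.argwhere(labels == lab)
            zvals = zm.z.data[labels == lab]
            centroid_vox = vox.mean(axis=0)
            centroid = aff[:3, :3] @ centroid_vox + aff[:3, 3]
            clusters.append(
                Cluster(
                    voxels=vox,
                    size=int(size),
                    peak_z=float(zvals.max()),
                    centroid_mm=tuple(float(c) for c in centroid),
                )
            )
    clusters.sort(key=lambda c: (-c.size, -c.peak_z, c.centroid_mm))
    return ClusterSet(clusters=clusters, z_threshold=z_threshold,
                      min_voxels=min_voxels, connectivity=connectivity)


@dataclass
class RegionalCalls:
    """Per-region positive/negative calls from surviving clusters."""

    calls: dict[str, bool]
    overlap_voxels: dict[str, int]

    def positive_regions(self) -> list[str]:
        return [r for r in REGION_NAMES if self.calls[r]]

    def to_dict(self) -> dict:
        return {
            r: {"call": "positive" if self.calls[r] else "negative",
                "overlap_voxels": self.overlap_voxels[r]}
            for r in REGION_NAMES
        }


def regional_positivity(cs: ClusterSet, vs: VOISet) -> RegionalCalls:
    """A region is positive iff any surviving cluster has >= 1 voxel in it."""
    cluster_map = np.zeros(vs.grid.dims, dtype=bool)
    for c in cs.clusters:
        cluster_map[tuple(c.voxels.T)] = True
    calls, overlaps = {}, {}
    for name in REGION_NAMES:
        ov = int((cluster_map & vs.region_masks[name].data).sum())
        overlaps[name] = ov
        calls[name] = ov >= 1
    return RegionalCalls(calls=calls, overlap_voxels=overlaps)


def render_overlay(
    zm: ZMap,
    anatomy: Volume,
    vs: VOISet,
    out_dir: str | Path,
    z_low: float = 2.6,
    z_high: float = 7.0,
    min_voxels: int | None = None,
    n_slices: int = 1,
    connectivity: int = 18,
) -> list[Path]:
    """Write axial/coronal/sagittal PNG slices of the Z overlay.

    The overlay shows voxels with Z in [z_low, z_high] (values above
    z_high saturate); if ``min_voxels`` is given, only voxels of clusters
    surviving that extent threshold are shown. The target-region contour
    is drawn in white. Returns the written paths — 3 per requested slice.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if z_low >= z_high:
        raise ValueError(f"z_low ({z_low}) must be < z_high ({z_high})")
    if not anatomy.grid.matches(zm.z.grid):
        raise ValueError("anatomy grid does not match Z-map grid")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    show = zm.z.data.copy()
    if min_voxels is not None:
        cs = threshold_clusters(zm, z_threshold=z_low, min_voxels=min_voxels,
                                connectivity=connectivity)
        keep = np.zeros(show.shape, dtype=bool)
        for c in cs.clusters:
            keep[tuple(c.voxels.T)] = True
        show[~keep] = 0.0
    overlay = np.ma.masked_less(show, z_low)

    dims = zm.z.grid.dims
    paths = []
    for axis, label in enumerate(("sagittal", "coronal", "axial")):
        centers = np.linspace(0, dims[axis] - 1, n_slices + 2)[1:-1].round().astype(int)
        for k, idx in enumerate(centers):
            sl = [slice(None)] * 3
            sl[axis] = idx
            sl = tuple(sl)
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(anatomy.data[sl].T, cmap="gray", origin="lower")
            ax.imshow(overlay[sl].T, cmap="hot", vmin=z_low, vmax=z_high,
                      origin="lower", interpolation="nearest")
            tgt = vs.target_mask.data[sl].T.astype(float)
            if tgt.any():
                ax.contour(tgt, levels=[0.5], colors="white", linewidths=0.6)
            ax.set_axis_off()
            p = out_dir / f"zmap_{label}_{k:02d}.png"
            fig.savefig(p, dpi=100, bbox_inches="tight")
            plt.close(fig)
            paths.append(p)
    return paths


def save_normative_db(db: NormativeDB, out_dir: str | Path) -> Path:
    """Persist as a directory: mean/sd/mask NIfTIs plus db.json metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(db.mean_volume, out_dir / "mean.nii.gz", dtype=np.float64)
    write_volume(db.sd_volume, out_dir / "sd.nii.gz", dtype=np.float64)
    write_mask(db.analysis_mask, out_dir / "mask.nii.gz")
    meta = {
        "tracer": db.tracer,
        "reference": db.reference,
        "n_controls": db.n_controls,
        "fwhm_mm": db.fwhm_mm,
        "cl_threshold": db.cl_threshold,
        "sd_ddof": db.sd_ddof,
        "excluded_controls": db.excluded,
    }
    (out_dir / "db.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def load_normative_db(db_dir: str | Path) -> NormativeDB:
    db_dir = Path(db_dir)
    meta = json.loads((db_dir / "db.json").read_text())
    mean = read_volume(db_dir / "mean.nii.gz")
    sd = read_volume(db_dir / "sd.nii.gz")
    mean.meta.update(fwhm_mm=meta["fwhm_mm"], reference=meta["reference"])
    sd.meta.update(fwhm_mm=meta["fwhm_mm"], reference=meta["reference"])
    mask = read_mask(db_dir / "mask.nii.gz", name="analysis")
    return NormativeDB(
        tracer=meta["tracer"],
        reference=meta["reference"],
        mean_volume=mean,
        sd_volume=sd,
        n_controls=int(meta["n_controls"]),
        analysis_mask=mask,
        cl_threshold=float(meta["cl_threshold"]),
        fwhm_mm=float(meta["fwhm_mm"]),
        excluded=list(meta.get("excluded_controls", [])),
        sd_ddof=int(meta.get("sd_ddof", 1)),
    )
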