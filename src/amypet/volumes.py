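"""Volume data model and basic image operations.

A :class:`Volume` couples a 3-D scalar array with a :class:`Grid3D`
(voxel-index -> world-mm affine, RAS+ convention, 0-based indices).
Everything downstream — SUVR extraction, normative statistics, Z-maps —
runs on these carriers, so the invariants enforced here (finite data,
invertible affine, shape/grid agreement) protect the whole pipeline.

The default analysis grid is the common 2 mm isotropic MNI152 grid,
91 x 109 x 91 voxels, so one voxel is 8 mm^3 and a 300-voxel cluster
is 2.4 cc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Grid3D",
    "Volume",
    "Mask",
    "DEFAULT_GRID",
    "FWHM_TO_SIGMA",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_to_grid",
    "gaussian_smooth",
    "set_origin",
]

#: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class Grid3D:
    """A 3-D sampling grid: dims plus a voxel-index -> world-mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel index (0-based) -> world mm, RAS+

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if not np.all(np.isfinite(aff)):
            raise ValueError("affine contains non-finite entries")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("degenerate affine (non-invertible)")
        if any(d < 1 for d in dims):
            raise ValueError(f"dims must all be >= 1, got {dims}")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        """Column norms of the linear part: physical size of one voxel step."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def world_center(self) -> np.ndarray:
        """World coordinates of the grid's geometric center."""
        c = (np.asarray(self.dims, dtype=float) - 1.0) / 2.0
        return self.affine[:3, :3] @ c + self.affine[:3, 3]

    def voxel_coords_world(self) -> np.ndarray:
        """(3, nx, ny, nz) array of world coordinates of every voxel center."""
        idx = np.indices(self.dims, dtype=float)
        flat = idx.reshape(3, -1)
        world = self.affine[:3, :3] @ flat + self.affine[:3, 3:4]
        return world.reshape((3,) + self.dims)

    def matches(self, other: "Grid3D", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )


def _mni_2mm_affine() -> np.ndarray:
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    # voxel (45, 63, 36) sits at the world origin (anterior commissure)
    aff[:3, 3] = [-90.0, -126.0, -72.0]
    return aff


#: 2 mm isotropic analysis grid (91 x 109 x 91), matching the MNI152 2 mm box.
DEFAULT_GRID = Grid3D(dims=(91, 109, 91), affine=_mni_2mm_affine())


@dataclass
class Volume:
    """A scalar 3-D image on a :class:`Grid3D`.

    ``meta`` carries free-form provenance tags (smoothing FWHM, reference
    normalization, ...) that downstream stages use to verify that inputs
    were prepared consistently.
    """

    grid: Grid3D
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"data shape {self.data.shape} != grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains NaN/Inf voxels")

    def with_data(self, data: np.ndarray, **meta_updates) -> "Volume":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Volume(grid=self.grid, data=data, meta=meta)


@dataclass
class Mask:
    """A binary region-of-interest on a :class:`Grid3D`."""

    grid: Grid3D
    data: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask {self.name!r} has values outside {{0,1}}")
        self.data = arr.astype(bool)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"mask {self.name!r}: shape {self.data.shape} != grid {self.grid.dims}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3 / 1000.0


def read_volume(path: str | Path) -> Volume:
    """Load a 3-D NIfTI image.

    Raises on missing files, non-3-D images, and non-finite voxels:
    silently zeroed NaNs would corrupt downstream VOI means.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got shape {data.shape} in {path}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains NaN/Inf voxels")
    grid = Grid3D(dims=tuple(data.shape), affine=np.asarray(img.affine))
    return Volume(grid=grid, data=np.asarray(data, dtype=np.float64),
                  meta={"source": str(path)})


def write_volume(v: Volume, path: str | Path, dtype=np.float32) -> None:
    """Write a Volume as NIfTI-1 (.nii or .nii.gz), float32 by default."""
    path = Path(path)
    img = nib.Nifti1Image(v.data.astype(dtype), v.grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path, name: str = "", threshold: float = 0.5) -> Mask:
    """Load a mask volume, binarizing at ``> threshold``."""
    v = read_volume(path)
    return Mask(grid=v.grid, data=(v.data > threshold).astype(np.uint8),
                name=name or Path(path).name)


def write_mask(m: Mask, path: str | Path) -> None:
    img = nib.Nifti1Image(m.data.astype(np.uint8), m.grid.affine)
    nib.save(img, str(path))


def _compose_voxel_map(source: Grid3D, target: Grid3D) -> np.ndarray:
    """4x4 map: target voxel index -> source voxel index."""
    return np.linalg.inv(source.affine) @ target.affine


def resample_to_grid(
    v: Volume, target: Grid3D, interpolation: str = "trilinear"
) -> Volume:
    """Resample a volume onto ``target`` by pull-back sampling.

    Each target voxel center is mapped through both affines into the
    source voxel space and sampled there; points outside the source
    field of view become 0.
    """
    order = _interp_order(interpolation)
    M = _compose_voxel_map(v.grid, target)
    out = ndimage.affine_transform(
        v.data, M[:3, :3], offset=M[:3, 3], output_shape=target.dims,
        order=order, mode="constant", cval=0.0, prefilter=False,
    )
    return Volume(grid=target, data=out, meta=dict(v.meta))


def _interp_order(interpolation: str) -> int:
    try:
        return {"nearest": 0, "trilinear": 1}[interpolation]
    except KeyError:
        raise ValueError(
            f"interpolation must be 'nearest' or 'trilinear', got {interpolation!r}"
        ) from None


def resample_mask_to_grid(m: Mask, target: Grid3D) -> Mask:
    """Masks travel by nearest-neighbor only, so they stay binary."""
    v = Volume(grid=m.grid, data=m.data.astype(np.float64))
    out = resample_to_grid(v, target, interpolation="nearest")
    return Mask(grid=target, data=(out.data > 0.5).astype(np.uint8), name=m.name)


def gaussian_smooth(v: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with the kernel width given as FWHM in mm.

    sigma per axis is fwhm * FWHM_TO_SIGMA divided by the voxel size on
    that axis. ``fwhm_mm = 0`` is the identity. The result records the
    applied FWHM in ``meta['fwhm_mm']`` (cumulative in quadrature if the
    input was already smoothed), which the normative-database stage uses
    to check subject/database consistency.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return v.with_data(v.data.copy(), fwhm_mm=v.meta.get("fwhm_mm", 0.0))
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in v.grid.voxel_size_mm]
    out = ndimage.gaussian_filter(v.data, sigma=sigma_vox, mode="constant", cval=0.0)
    prev = float(v.meta.get("fwhm_mm", 0.0))
    return v.with_data(out, fwhm_mm=math.hypot(prev, fwhm_mm))


def set_origin(v: Volume, voxel_index: tuple[int, int, int]) -> Volume:
    """Translate the affine so ``voxel_index`` maps to world (0, 0, 0).

    This is the programmatic stand-in for manually placing the origin at
    the anterior commissure before registration; the data itself is
    untouched.
    """
    idx = np.asarray(voxel_index, dtype=float)
    if idx.shape != (3,):
        raise ValueError("voxel_index must be a length-3 integer triple")
    if np.any(idx < 0) or np.any(idx >= np.asarray(v.grid.dims)):
        raise IndexError(f"voxel_index {voxel_index} out of bounds {v.grid.dims}")
    aff = v.grid.affine.copy()
    aff[:3, 3] = -aff[:3, :3] @ idx
    grid = Grid3D(dims=v.grid.dims, affine=aff)
    return Volume(grid=grid, data=v.data.copy(), meta=dict(v.meta))
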