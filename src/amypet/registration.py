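"""Linear registration to template space and application of deformations.

Rigid (6-parameter) and affine (12-parameter) registration maximize
normalized mutual information (NMI) between the fixed image and the
resampled moving image, using a two-level multi-resolution pyramid
(coarse ~4 mm, then full resolution) and derivative-free Powell search
with seeded restarts. The convention throughout: a
:class:`LinearTransform` maps *moving-world* coordinates to
*fixed-world* coordinates, and images are moved by pull-back sampling
(each output voxel samples the moving image at ``t^-1 x``).

Nonlinear warping to MNI space (unified-segmentation style) is *not*
re-implemented: :func:`apply_deformation` consumes an externally
computed displacement field (mm, on the analysis grid), and the affine
mode of :func:`register_linear` serves as the built-in fallback
normalization when no field is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage, optimize

from .volumes import Grid3D, Volume, gaussian_smooth, resample_to_grid, _interp_order

__all__ = [
    "LinearTransform",
    "DeformationField",
    "RegistrationOptions",
    "register_linear",
    "apply_linear",
    "apply_deformation",
    "normalized_mutual_information",
    "save_transform",
    "load_transform",
    "read_deformation",
    "write_deformation",
]


@dataclass(frozen=True)
class LinearTransform:
    """4x4 world->world map (moving mm -> fixed mm)."""

    matrix: np.ndarray
    kind: str  # "rigid" | "affine"
    nmi: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(M[:3, :3])) < 1e-12:
            raise ValueError("degenerate transform")
        if self.kind not in ("rigid", "affine"):
            raise ValueError(f"kind must be 'rigid' or 'affine', got {self.kind!r}")
        if self.kind == "rigid":
            R = M[:3, :3]
            if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
                raise ValueError("rigid transform has non-orthonormal rotation block")
        object.__setattr__(self, "matrix", M)

    def inverse(self) -> "LinearTransform":
        return LinearTransform(np.linalg.inv(self.matrix), kind=self.kind)

    def compose(self, other: "LinearTransform") -> "LinearTransform":
        """self after other (applies ``other`` first)."""
        kind = "rigid" if self.kind == other.kind == "rigid" else "affine"
        return LinearTransform(self.matrix @ other.matrix, kind=kind)

    def rotation_angle_deg(self) -> float:
        """Total rotation angle of the orthogonal part (polar decomposition)."""
        U, _, Vt = np.linalg.svd(self.matrix[:3, :3])
        R = U @ Vt
        if np.linalg.det(R) < 0:
            R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
        c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))


def identity_transform(kind: str = "rigid") -> LinearTransform:
    return LinearTransform(np.eye(4), kind=kind)


@dataclass
class DeformationField:
    """Per-voxel displacement (mm, world frame) on the target analysis grid."""

    grid: Grid3D
    displacement: np.ndarray  # shape dims + (3,), mm

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=float)
        if disp.shape != self.grid.dims + (3,):
            raise ValueError(
                f"displacement shape {disp.shape} != grid dims + (3,)"
            )
        if not np.all(np.isfinite(disp)):
            raise ValueError("displacement field contains non-finite values")
        self.displacement = disp


@dataclass
class RegistrationOptions:
    """Tunables for :func:`register_linear` (kept in config, not code)."""

    seed: int = 0
    restarts: int = 3          # multi-start at the coarse level
    bins: int = 64
    coarse_mm: float = 4.0
    maxiter: int = 8           # Powell iterations, coarse level
    fine_maxiter: int = 3      # warm-started refinement at full resolution
    xtol: float = 0.01         # ~0.01 mm / 0.01 deg line-search tolerance
    ftol: float = 1e-6
    crop_margin_mm: float = 12.0  # content crop around the fixed image
    # seeded restart perturbation scales
    perturb_translation_mm: float = 1.0
    perturb_rotation_deg: float = 1.0
    perturb_scale_pct: float = 0.5


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def normalized_mutual_information(
    a: np.ndarray, b: np.ndarray, bins: int = 64,
    a_range: tuple[float, float] | None = None,
    b_range: tuple[float, float] | None = None,
) -> float:
    """Studholme NMI = (H(a) + H(b)) / H(a, b), from a joint histogram.

    Intensity ranges default to each image's 1st-99th percentile; values
    outside are clipped into the edge bins.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a_range is None:
        a_range = tuple(np.percentile(a, (1, 99)))
    if b_range is None:
        b_range = tuple(np.percentile(b, (1, 99)))
    if a_range[1] <= a_range[0] or b_range[1] <= b_range[0]:
        raise ValueError("constant image: NMI undefined")
    a = np.clip(a, *a_range)
    b = np.clip(b, *b_range)
    joint, _, _ = np.histogram2d(a, b, bins=bins, range=[a_range, b_range])
    p = joint / joint.sum()
    ha = _entropy(p.sum(axis=1))
    hb = _entropy(p.sum(axis=0))
    hab = _entropy(p.ravel())
    if hab == 0:
        return 2.0
    return (ha + hb) / hab


def _rot_xyz(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix from Euler angles in degrees, R = Rz @ Ry @ Rx."""
    rx, ry, rz = np.radians([rx, ry, rz])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _params_to_matrix(params: np.ndarray, center: np.ndarray, kind: str) -> np.ndarray:
    """Build the 4x4 from optimizer parameters.

    Layout: [tx, ty, tz, rx, ry, rz] (+ [sx, sy, sz, kxy, kxz, kyz] for
    affine). Translations in mm, rotations in degrees, scales as percent
    deviation from 1, shears in percent — all O(1) for Powell.
    Rotation/scale act about ``center`` (fixed-image world center).
    """
    t = params[:3]
    R = _rot_xyz(*params[3:6])
    A = R
    if kind == "affine":
        s = 1.0 + params[6:9] / 100.0
        k = params[9:12] / 100.0
        S = np.diag(s)
        K = np.array([[1.0, k[0], k[1]], [0.0, 1.0, k[2]], [0.0, 0.0, 1.0]])
        A = R @ K @ S
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = t + center - A @ center
    return M


def _n_params(kind: str) -> int:
    return 6 if kind == "rigid" else 12


def _coarse_grid(grid: Grid3D, level_mm: float) -> Grid3D:
    """A grid with ~level_mm voxels covering the same field of view."""
    vox = np.asarray(grid.voxel_size_mm)
    factor = np.maximum(1.0, level_mm / vox)
    dims = tuple(int(max(2, np.ceil(d / f))) for d, f in zip(grid.dims, factor))
    aff = grid.affine.copy()
    aff[:3, :3] = grid.affine[:3, :3] @ np.diag(factor)
    return Grid3D(dims=dims, affine=aff)


def _resample_through(
    moving: Volume, matrix: np.ndarray, target: Grid3D, order: int = 1
) -> np.ndarray:
    """Sample the moving image on ``target`` through world map ``matrix``
    (moving world -> target world); pull-back uses the inverse."""
    M = (
        np.linalg.inv(moving.grid.affine)
        @ np.linalg.inv(matrix)
        @ target.affine
    )
    return ndimage.affine_transform(
        moving.data, M[:3, :3], offset=M[:3, 3], output_shape=target.dims,
        order=order, mode="constant", cval=0.0, prefilter=False,
    )


def _crop_to_content(v: Volume, margin_mm: float) -> Volume:
    """Crop to the bounding box of above-background voxels (plus margin).

    The crop only changes which fixed-grid voxels enter the NMI
    histogram; the affine is shifted so world coordinates are untouched.
    """
    thr = float(np.percentile(v.data, 50))
    nz = np.argwhere(v.data > thr + 1e-12 * max(1.0, abs(thr)))
    if nz.size == 0:
        return v
    margin = np.ceil(margin_mm / np.asarray(v.grid.voxel_size_mm)).astype(int)
    lo = np.maximum(nz.min(axis=0) - margin, 0)
    hi = np.minimum(nz.max(axis=0) + margin + 1, v.grid.dims)
    aff = v.grid.affine.copy()
    aff[:3, 3] = aff[:3, :3] @ lo + aff[:3, 3]
    grid = Grid3D(dims=tuple(hi - lo), affine=aff)
    data = v.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return Volume(grid=grid, data=data, meta=dict(v.meta))


def _digitize(a: np.ndarray, rng: tuple[float, float], bins: int) -> np.ndarray:
    scaled = (a.ravel() - rng[0]) / (rng[1] - rng[0]) * bins
    return np.clip(scaled.astype(np.int64), 0, bins - 1)


def _nmi_digitized(fix_idx: np.ndarray, mov: np.ndarray,
                   mov_range: tuple[float, float], bins: int) -> float:
    """NMI with the fixed image pre-binned (hot loop of registration)."""
    mov_idx = _digitize(mov, mov_range, bins)
    joint = np.bincount(fix_idx * bins + mov_idx, minlength=bins * bins)
    p = joint / joint.sum()
    ha = _entropy(p.reshape(bins, bins).sum(axis=1))
    hb = _entropy(p.reshape(bins, bins).sum(axis=0))
    hab = _entropy(p)
    return 2.0 if hab == 0 else (ha + hb) / hab


def register_linear(
    moving: Volume,
    fixed: Volume,
    kind: str = "rigid",
    opts: RegistrationOptions | None = None,
) -> LinearTransform:
    """Estimate the NMI-maximizing linear map from moving to fixed space.

    Two Powell passes: a coarse grid (~``opts.coarse_mm``) with seeded
    multi-start to escape shallow local optima, then a warm-started
    refinement at the fixed grid's native resolution. The fixed image is
    cropped to its content bounding box so the joint histogram is not
    dominated by empty background. Deterministic for a given
    ``opts.seed``.
    """
    if kind not in ("rigid", "affine"):
        raise ValueError(f"kind must be 'rigid' or 'affine', got {kind!r}")
    for name, v in (("moving", moving), ("fixed", fixed)):
        if np.ptp(v.data) == 0:
            raise ValueError(f"{name} image is constant; registration undefined")
    opts = opts or RegistrationOptions()
    rng = np.random.default_rng(opts.seed)
    center = fixed.grid.world_center()
    n = _n_params(kind)

    fixed_c = _crop_to_content(fixed, opts.crop_margin_mm)
    fine_mm = float(min(fixed.grid.voxel_size_mm))
    levels: list[tuple[Grid3D, Volume, Volume, int]] = []
    if opts.coarse_mm > fine_mm:
        fix_l = resample_to_grid(
            gaussian_smooth(fixed_c, opts.coarse_mm),
            _coarse_grid(fixed_c.grid, opts.coarse_mm),
        )
        levels.append(
            (fix_l.grid, fix_l, gaussian_smooth(moving, opts.coarse_mm),
             opts.maxiter)
        )
    levels.append((fixed_c.grid, fixed_c, moving, opts.fine_maxiter))

    params = np.zeros(n)
    best_nmi = -np.inf
    converged = True

    for li, (grid_l, fix_l, mov_l, maxiter) in enumerate(levels):
        fix_range = tuple(np.percentile(fix_l.data, (1, 99)))
        mov_range = tuple(np.percentile(mov_l.data, (1, 99)))
        fix_idx = _digitize(np.clip(fix_l.data, *fix_range), fix_range, opts.bins)

        def cost(p: np.ndarray) -> float:
            M = _params_to_matrix(p, center, kind)
            resampled = _resample_through(mov_l, M, grid_l)
            return -_nmi_digitized(fix_idx, resampled, mov_range, opts.bins)

        starts = [params.copy()]
        if li == 0:
            for _ in range(max(0, opts.restarts - 1)):
                pert = np.zeros(n)
                pert[:3] = rng.normal(0, opts.perturb_translation_mm, 3)
                pert[3:6] = rng.normal(0, opts.perturb_rotation_deg, 3)
                if kind == "affine":
                    pert[6:] = rng.normal(0, opts.perturb_scale_pct, 6)
                starts.append(params + pert)

        best_p, best_f, best_ok = None, np.inf, True
        for p0 in starts:
            res = optimize.minimize(
                cost, p0, method="Powell",
                options={"maxiter": maxiter, "xtol": opts.xtol,
                         "ftol": opts.ftol},
            )
            if res.fun < best_f:
                best_p, best_f = np.asarray(res.x, dtype=float), float(res.fun)
                best_ok = bool(res.success)
        params = best_p
        best_nmi = -best_f
        if li == 0 and not best_ok:
            # the fine pass is iteration-bounded by design; only an
            # unconverged winning coarse search is worth flagging
            converged = False

    if not converged:
        warnings.warn(
            "registration optimizer hit the iteration limit; "
            "returning best transform found", RuntimeWarning,
        )
    M = _params_to_matrix(params, center, kind)
    if kind == "rigid":
        # re-orthonormalize: Powell works in exact Euler angles, but guard
        # against accumulated floating-point drift
        U, _, Vt = np.linalg.svd(M[:3, :3])
        M[:3, :3] = U @ Vt
    return LinearTransform(M, kind=kind, nmi=best_nmi, converged=converged)


def apply_linear(
    v: Volume, t: LinearTransform, target: Grid3D,
    interpolation: str = "trilinear",
) -> Volume:
    """Resample ``v`` onto ``target`` through the world map ``t``."""
    order = _interp_order(interpolation)
    out = _resample_through(v, t.matrix, target, order=order)
    return Volume(grid=target, data=out, meta=dict(v.meta))


def apply_deformation(
    v: Volume, d: DeformationField, interpolation: str = "trilinear"
) -> Volume:
    """Warp ``v`` onto the deformation grid by pull-back through the field.

    Output voxel at world point x samples the source at x + u(x); a zero
    field therefore reduces to plain resampling onto ``d.grid``.
    """
    order = _interp_order(interpolation)
    world = d.grid.voxel_coords_world()  # (3, nx, ny, nz)
    src_world = world + np.moveaxis(d.displacement, -1, 0)
    inv = np.linalg.inv(v.grid.affine)
    src_vox = np.einsum("ij,j...->i...", inv[:3, :3], src_world) + inv[:3, 3].reshape(
        3, 1, 1, 1
    )
    out = ndimage.map_coordinates(
        v.data, src_vox, order=order, mode="constant", cval=0.0, prefilter=False
    )
    return Volume(grid=d.grid, data=out, meta=dict(v.meta))


def save_transform(t: LinearTransform, path: str | Path) -> None:
    """Serialize as plain text: one 4x4 row per line, kind in a comment."""
    path = Path(path)
    header = f"kind: {t.kind}"
    np.savetxt(path, t.matrix, header=header)


def load_transform(path: str | Path) -> LinearTransform:
    path = Path(path)
    kind = "affine"
    with open(path) as fh:
        first = fh.readline()
        if "kind:" in first:
            kind = first.split("kind:")[1].strip()
    M = np.loadtxt(path)
    return LinearTransform(M, kind=kind)


def write_deformation(d: DeformationField, path: str | Path) -> None:
    """Write as 5-D NIfTI (x, y, z, 1, 3) displacement in mm."""
    arr = d.displacement.reshape(d.grid.dims + (1, 3)).astype(np.float32)
    img = nib.Nifti1Image(arr, d.grid.affine)
    img.header["intent_code"] = 1006  # displacement vector
    nib.save(img, str(path))


def read_deformation(path: str | Path) -> DeformationField:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 5 and arr.shape[3] == 1 and arr.shape[4] == 3:
        arr = arr[:, :, :, 0, :]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(
            f"expected (x, y, z, 1, 3) or (x, y, z, 3) displacement, "
            f"got shape {arr.shape}"
        )
    grid = Grid3D(dims=arr.shape[:3], affine=np.asarray(img.affine))
    return DeformationField(grid=grid, displacement=np.asarray(arr, dtype=float))
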