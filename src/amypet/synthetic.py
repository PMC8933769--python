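"""Synthetic phantoms, VOI sets and cohorts with known ground truth.

Every processing stage of the package is exercised on programmatically
generated data: a geometric "brain" phantom (ellipsoidal cerebrum with a
cortical shell, striatal blobs, cerebellum, pons and a white-matter
core), a matching VOI set with the four reference regions, the global
target and the five reporting subregions, and cohort generators that
draw amyloid-negative controls and lesioned patients around a common
template.

The phantoms are geometric rather than anatomical on purpose: the
quantification math (VOI means, SUVR ratios, Z statistics, cluster
extents) is geometry-agnostic, and synthetic geometry gives exact ground
truth. Uptake is piecewise-constant per compartment, optionally blurred
by a Gaussian scanner PSF and degraded with additive Gaussian noise
(SD relative to the background level). This is a statistics testbed,
not a PET physics model — see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centiloid import default_calibration_table
from .voi import REFERENCE_NAMES, REGION_NAMES, TARGET_NAME, VOISet, mask_mean
from .volumes import DEFAULT_GRID, Grid3D, Mask, Volume, gaussian_smooth

__all__ = [
    "PhantomSpec",
    "make_voi_set",
    "make_wm_mask",
    "make_phantom",
    "make_cohort",
    "CohortGenerator",
    "CohortBundle",
    "CONTROL_UPTAKE",
]


def _unit_coords(grid: Grid3D) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinates normalized to [0, 1] per axis."""
    axes = [np.linspace(0.0, 1.0, d) for d in grid.dims]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_rho(u, c, r):
    x, y, z = u
    return np.sqrt(
        ((x - c[0]) / r[0]) ** 2
        + ((y - c[1]) / r[1]) ** 2
        + ((z - c[2]) / r[2]) ** 2
    )


# geometry in grid-fraction coordinates (axis fraction 0..1); proportions are
# chosen so every mask clears its size floor even on the smallest admissible
# grid (40 voxels per axis), which makes some structures generously sized
_CEREBRUM_C, _CEREBRUM_R = (0.50, 0.55, 0.62), (0.36, 0.36, 0.30)
_SHELL_INNER = 0.78
_WM_OUTER = 0.70
_Z_CUT = -0.60          # inferior cut of the cortical shell, in dz/rz units
_CEREBELLUM_C, _CEREBELLUM_R = (0.50, 0.28, 0.20), (0.22, 0.16, 0.14)
_CEREBGRY_INNER = 0.60
_PONS_C, _PONS_R = (0.50, 0.62, 0.16), (0.16, 0.14, 0.11)
_STRIATUM_DX, _STRIATUM_R = 0.13, (0.09, 0.105, 0.09)


_GEOMETRY_CACHE: dict[tuple, dict[str, np.ndarray]] = {}


def _geometry(grid: Grid3D) -> dict[str, np.ndarray]:
    key = (grid.dims, grid.affine.tobytes())
    if key in _GEOMETRY_CACHE:
        return _GEOMETRY_CACHE[key]
    g = _compute_geometry(grid)
    if len(_GEOMETRY_CACHE) > 4:
        _GEOMETRY_CACHE.clear()
    _GEOMETRY_CACHE[key] = g
    return g


def _compute_geometry(grid: Grid3D) -> dict[str, np.ndarray]:
    if min(grid.dims) < 40:
        raise ValueError(
            f"grid too small for the synthetic brain: dims {grid.dims}, "
            "need >= 40 voxels per axis"
        )
    u = _unit_coords(grid)
    x, y, z = u
    c, r = _CEREBRUM_C, _CEREBRUM_R
    rho = _ellipsoid_rho(u, c, r)
    dxn = (x - c[0]) / r[0]
    dyn = (y - c[1]) / r[1]
    dzn = (z - c[2]) / r[2]
    cerebrum = rho <= 1.0
    above_cut = np.broadcast_to(dzn > _Z_CUT, grid.dims)
    shell = (rho >= _SHELL_INNER) & cerebrum & above_cut

    dxn, dyn, dzn = np.broadcast_arrays(dxn, dyn, dzn)
    frontal = shell & (dyn > 0.32)
    pcc = shell & ~frontal & (dyn < -0.25) & (np.abs(dxn) < 0.45) & (dzn > 0.0)
    parietal = shell & ~frontal & ~pcc & (dzn > 0.50)
    temporal = (
        shell & ~frontal & ~pcc & ~parietal & (dzn < 0.12) & (np.abs(dxn) > 0.42)
    )

    striatum = np.zeros(grid.dims, dtype=bool)
    for sgn in (-1.0, 1.0):
        cs = (c[0] + sgn * _STRIATUM_DX, c[1] + 0.02, c[2] - 0.03)
        striatum |= _ellipsoid_rho(u, cs, _STRIATUM_R) <= 1.0

    wm = (rho <= _WM_OUTER) & above_cut & ~striatum

    cb_rho = _ellipsoid_rho(u, _CEREBELLUM_C, _CEREBELLUM_R)
    cerebellum = (cb_rho <= 1.0) & ~cerebrum
    cerebgry = cerebellum & (cb_rho >= _CEREBGRY_INNER)
    pons = (_ellipsoid_rho(u, _PONS_C, _PONS_R) <= 1.0) & ~cerebellum & ~cerebrum

    target = shell | striatum
    return {
        "WhlCbl": cerebellum,
        "CerebGry": cerebgry,
        "Pons": pons,
        "WhlCblBrnStm": cerebellum | pons,
        TARGET_NAME: target,
        "pcc_precuneus": pcc,
        "frontal": frontal,
        "temporal": temporal,
        "parietal": parietal,
        "striatum": striatum,
        "wm": wm,
        "brain": cerebrum | cerebellum | pons,
    }


def make_voi_set(grid: Grid3D = DEFAULT_GRID) -> VOISet:
    """Geometric VOI set satisfying all VOISet invariants.

    Reference masks come out with >= 500 voxels and each reporting region
    with >= 400 voxels on any admissible grid (>= 40 voxels per axis).
    """
    g = _geometry(grid)
    mk = lambda name: Mask(grid=grid, data=g[name].astype(np.uint8), name=name)
    vs = VOISet(
        reference_masks={n: mk(n) for n in REFERENCE_NAMES},
        target_mask=mk(TARGET_NAME),
        region_masks={n: mk(n) for n in REGION_NAMES},
    )
    for n in REFERENCE_NAMES:
        if vs.reference_masks[n].n_voxels < 500:
            raise ValueError(f"reference mask {n!r} smaller than 500 voxels")
    for n in REGION_NAMES:
        if vs.region_masks[n].n_voxels < 400:
            raise ValueError(f"region mask {n!r} smaller than 400 voxels")
    return vs


def make_wm_mask(grid: Grid3D = DEFAULT_GRID) -> Mask:
    """Deep white-matter compartment of the phantom (high nonspecific uptake)."""
    g = _geometry(grid)
    return Mask(grid=grid, data=g["wm"].astype(np.uint8), name="wm")


@dataclass
class PhantomSpec:
    """Generative parameters of a single phantom PET volume."""

    grid: Grid3D = DEFAULT_GRID
    region_uptake: dict[str, float] = field(default_factory=dict)
    background: float = 1.0
    wm_uptake: float = 1.8
    noise_sd: float = 0.0          # relative to background
    fwhm_blur_mm: float = 0.0      # scanner PSF emulation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background < 0 or self.wm_uptake < 0:
            raise ValueError("uptake values must be >= 0")
        for k, v in self.region_uptake.items():
            if v < 0:
                raise ValueError(f"negative uptake for {k!r}")
        if self.noise_sd < 0 or self.fwhm_blur_mm < 0:
            raise ValueError("noise_sd and fwhm_blur_mm must be >= 0")


# painting order: unions first so that specific compartments override
_PAINT_ORDER = (
    "WhlCblBrnStm", "WhlCbl", "CerebGry", "Pons", TARGET_NAME,
) + REGION_NAMES


def _paint(spec: PhantomSpec, g: dict[str, np.ndarray]) -> np.ndarray:
    data = np.zeros(spec.grid.dims)
    data[g["brain"]] = spec.background
    data[g["wm"]] = spec.wm_uptake
    for name in _PAINT_ORDER:
        if name in spec.region_uptake:
            data[g[name]] = spec.region_uptake[name]
    return data


def make_phantom(
    spec: PhantomSpec, vs: VOISet | None = None
) -> tuple[Volume, dict]:
    """Build a phantom PET volume and its exact ground truth.

    Ground-truth SUVRs are mask means over the *pre-blur, pre-noise*
    piecewise volume (exact for any uptake configuration); ground-truth
    CL values follow from the published conversion coefficients for
    every available (tracer, reference) pair.
    """
    if vs is None:
        vs = make_voi_set(spec.grid)
    g = _geometry(spec.grid)
    clean = _paint(spec, g)
    clean_vol = Volume(grid=spec.grid, data=clean)

    table = default_calibration_table()
    t_mean = mask_mean(clean_vol, vs.target_mask)
    gt_suvr, gt_cl = {}, {}
    for ref in REFERENCE_NAMES:
        r_mean = mask_mean(clean_vol, vs.reference_masks[ref])
        if r_mean > 0:
            gt_suvr[ref] = t_mean / r_mean
    for tracer, ref in table.pairs():
        if ref in gt_suvr:
            gt_cl[f"{tracer}:{ref}"] = table.get(tracer, ref).to_cl(gt_suvr[ref])

    data = clean
    vol = Volume(grid=spec.grid, data=data, meta={"phantom_seed": spec.seed})
    if spec.fwhm_blur_mm > 0:
        vol = gaussian_smooth(vol, spec.fwhm_blur_mm)
        vol.meta.pop("fwhm_mm", None)  # PSF blur is physics, not processing
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = vol.data + rng.normal(
            0.0, spec.noise_sd * spec.background, size=spec.grid.dims
        )
        vol = vol.with_data(noisy)
    return vol, {"suvr": gt_suvr, "cl": gt_cl}


#: default control-template uptake (relative count units): low cortical
#: binding typical of a young amyloid-negative subject (PiB/WhlCbl CL ~ 4),
#: high nonspecific white matter, reference compartments near background.
CONTROL_UPTAKE = {
    TARGET_NAME: 1.05,
    "WhlCbl": 1.00,
    "CerebGry": 0.95,
    "Pons": 1.05,
}


class CohortGenerator:
    """Draws control and patient volumes around a shared template.

    Controls are i.i.d. around the template: each compartment's uptake is
    jittered multiplicatively (between-subject SD ``between_subject_sd``,
    default 0.005) and voxelwise Gaussian noise (SD ``noise_sd`` relative
    to background, default 0.25 — heavily suppressed later by the 8 mm
    pipeline smoothing) is added. Patients get an extra compact lesion
    inside a reporting region, with amplitude expressed in units of the
    control database's post-pipeline voxelwise SD, so a "5 SD" lesion
    means five control standard deviations after smoothing and reference
    normalization.
    """

    def __init__(
        self,
        grid: Grid3D = DEFAULT_GRID,
        uptake: dict[str, float] | None = None,
        background: float = 1.0,
        wm_uptake: float = 1.8,
        noise_sd: float = 0.25,
        between_subject_sd: float = 0.005,
        tracer: str = "PiB",
        reference: str = "WhlCbl",
        fwhm_mm: float = 8.0,
        cl_threshold: float = 10.0,
        seed: int = 0,
    ):
        self.grid = grid
        self.uptake = dict(CONTROL_UPTAKE if uptake is None else uptake)
        self.background = background
        self.wm_uptake = wm_uptake
        self.noise_sd = noise_sd
        self.between_subject_sd = between_subject_sd
        self.tracer = tracer
        self.reference = reference
        self.fwhm_mm = fwhm_mm
        self.cl_threshold = cl_threshold
        self.seed = seed
        self.vs = make_voi_set(grid)
        self.wm_mask = make_wm_mask(grid)
        self._g = _geometry(grid)
        self._table = default_calibration_table()
        self._db = None
        self._controls_cache: dict[int, list] = {}
        self._lesion_gain_cache: dict[tuple[str, int], float] = {}

    # -- generative model ------------------------------------------------

    def _jittered_spec(self, rng: np.random.Generator) -> PhantomSpec:
        jit = lambda v: v * (1.0 + rng.normal(0.0, self.between_subject_sd))
        uptake = {k: jit(v) for k, v in self.uptake.items()}
        return PhantomSpec(
            grid=self.grid,
            region_uptake=uptake,
            background=self.background,
            wm_uptake=jit(self.wm_uptake),
            noise_sd=0.0,
            fwhm_blur_mm=0.0,
        )

    def draw_control(self, rng: np.random.Generator) -> tuple[Volume, float]:
        """One raw (unsmoothed, unnormalized) control volume and its true CL."""
        spec = self._jittered_spec(rng)
        clean = _paint(spec, self._g)
        noisy = clean + rng.normal(
            0.0, self.noise_sd * self.background, size=self.grid.dims
        )
        vol = Volume(grid=self.grid, data=noisy)
        clean_vol = Volume(grid=self.grid, data=clean)
        suvr = (
            mask_mean(clean_vol, self.vs.target_mask)
            / mask_mean(clean_vol, self.vs.reference_masks[self.reference])
        )
        cl = self._table.get(self.tracer, self.reference).to_cl(suvr)
        return vol, float(cl)

    def controls(self, n: int) -> list[tuple[Volume, float]]:
        if n not in self._controls_cache:
            rng = np.random.default_rng(self.seed)
            self._controls_cache[n] = [self.draw_control(rng) for _ in range(n)]
        return self._controls_cache[n]

    def normative_db(self, n_controls: int):
        """Build (and cache) the normative database from ``n_controls`` draws."""
        from .zmap import build_normative_db

        if self._db is None or self._db.n_controls != n_controls:
            self._db = build_normative_db(
                self.controls(n_controls),
                self.vs,
                tracer=self.tracer,
                reference=self.reference,
                fwhm_mm=self.fwhm_mm,
                cl_threshold=self.cl_threshold,
                wm_mask=self.wm_mask,
            )
        return self._db

    def lesion_voxels(self, region: str, n_voxels: int) -> np.ndarray:
        """A compact blob of ``n_voxels`` region voxels nearest the centroid."""
        mask = self.vs.region_masks[region].data
        vox = np.argwhere(mask)
        if len(vox) < n_voxels:
            raise ValueError(
                f"region {region!r} has {len(vox)} voxels < lesion size {n_voxels}"
            )
        centroid = vox.mean(axis=0)
        d = np.linalg.norm(vox - centroid, axis=1)
        return vox[np.argsort(d)[:n_voxels]]

    def _lesion_gain(self, region: str, n_voxels: int,
                     idx: np.ndarray) -> float:
        """Pre-compensation for pipeline smoothing of a lesion blob.

        The requested effect size is defined *after* processing, but the
        raw injection is attenuated by the pipeline's Gaussian smoothing
        (a thin cortical blob loses roughly a third of its amplitude at
        8 mm FWHM). Scaling the raw amplitude by the reciprocal of the
        median smoothed-indicator value over the lesion makes the median
        delivered amplitude equal the nominal effect.
        """
        key = (region, n_voxels)
        if key not in self._lesion_gain_cache:
            if self.fwhm_mm <= 0:
                gain = 1.0
            else:
                ind = np.zeros(self.grid.dims)
                ind[tuple(idx.T)] = 1.0
                from .volumes import gaussian_smooth
                att = gaussian_smooth(
                    Volume(grid=self.grid, data=ind), self.fwhm_mm
                ).data[tuple(idx.T)]
                gain = 1.0 / float(np.median(att))
            self._lesion_gain_cache[key] = gain
        return self._lesion_gain_cache[key]

    def draw_patient(
        self,
        rng: np.random.Generator,
        effect_profile: dict[str, float],
        n_lesion_voxels: int = 600,
        db=None,
    ) -> tuple[Volume, dict[str, bool]]:
        """A control-like draw plus lesions per ``effect_profile``.

        ``effect_profile`` maps region name -> effect size in control-SD
        units, defined after processing: the raw-count amplitude is
        effect * median control SD over the lesion * the reference
        level, divided by the median smoothing attenuation of the lesion
        blob, so the median delivered Z over the lesion sits at the
        requested level.
        """
        if db is None:
            raise ValueError("draw_patient needs the normative database "
                             "to scale effects in control-SD units")
        vol, _cl = self.draw_control(rng)
        data = vol.data
        truth = {r: False for r in REGION_NAMES}
        ref_level = self.uptake.get(self.reference, self.background)
        for region, z_effect in effect_profile.items():
            if z_effect == 0:
                continue
            idx = self.lesion_voxels(region, n_lesion_voxels)
            sd_med = float(np.median(db.sd_volume.data[tuple(idx.T)]))
            gain = self._lesion_gain(region, n_lesion_voxels, idx)
            data[tuple(idx.T)] += z_effect * sd_med * ref_level * gain
            truth[region] = z_effect > 0
        return vol.with_data(data), truth


@dataclass
class CohortBundle:
    """A fully materialized synthetic cohort with ground truth."""

    generator: CohortGenerator
    controls: list[tuple[Volume, float]]
    patients: list[tuple[Volume, dict[str, bool]]]
    effect_profile: dict[str, float]

    @property
    def vs(self) -> VOISet:
        return self.generator.vs

    @property
    def wm_mask(self) -> Mask:
        return self.generator.wm_mask


def make_cohort(
    n_controls: int,
    n_patients: int,
    effect_profile: dict[str, float] | None = None,
    seed: int = 0,
    n_lesion_voxels: int = 600,
    **generator_kwargs,
) -> CohortBundle:
    """Controls plus patients with region-specific effects, ground truth known.

    Patients require ``n_controls >= 2`` because the lesion amplitude is
    scaled by the control database's voxelwise SD.
    """
    if n_controls < 2:
        raise ValueError("need >= 2 controls")
    effect_profile = dict(effect_profile or {})
    gen = CohortGenerator(seed=seed, **generator_kwargs)
    controls = gen.controls(n_controls)
    patients = []
    if n_patients:
        db = gen.normative_db(n_controls)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        for _ in range(n_patients):
            patients.append(
                gen.draw_patient(rng, effect_profile, n_lesion_voxels, db=db)
            )
    return CohortBundle(
        generator=gen, controls=controls, patients=patients,
        effect_profile=effect_profile,
    )
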