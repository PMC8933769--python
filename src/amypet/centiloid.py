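"""SUVR computation and conversion to the Centiloid (CL) scale.

The Centiloid scale anchors amyloid-PET quantification across tracers and
methods: 0 is the typical young amyloid-negative level and 100 the typical
Alzheimer's-disease level. For a given tracer and reference region the map
from SUVR to CL is linear,

    CL = intercept + slope * SUVR,

with published per-(tracer, reference) coefficients. The shipped
calibration table covers the 14 published pairs for the five tracers
(11C-PiB, 18F-florbetapir, 18F-flutemetamol, 18F-florbetaben,
18F-NAV4694) against the four standard reference regions; the six pairs
with no published conversion (florbetapir and flutemetamol against
CerebGry, WhlCblBrnStm and Pons) raise :class:`NoConversionError`.

The Klunk-style validation bands for a pipeline replicating published CL
values are: regression slope in [0.98, 1.02], intercept in [-2, 2] CL,
and R^2 > 0.98.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .voi import VOISet, mask_mean, TARGET_NAME
from .volumes import Volume

__all__ = [
    "TRACERS",
    "TRACER_ALIASES",
    "REFERENCE_ALIASES",
    "NoConversionError",
    "TracerCalibration",
    "CalibrationTable",
    "load_calibration_table",
    "SUVRResult",
    "CentiloidResult",
    "ValidationResult",
    "compute_suvr",
    "suvr_to_centiloid",
    "validate_against_reference",
]

TRACERS = ("PiB", "florbetapir", "flutemetamol", "florbetaben", "NAV4694")

#: CLI shorthand -> canonical tracer name
TRACER_ALIASES = {
    "pib": "PiB",
    "fbp": "florbetapir",
    "flute": "flutemetamol",
    "fbb": "florbetaben",
    "nav": "NAV4694",
}

#: CLI shorthand -> canonical reference-VOI name
REFERENCE_ALIASES = {
    "whlcbl": "WhlCbl",
    "cerebgry": "CerebGry",
    "whlcblbrnstm": "WhlCblBrnStm",
    "pons": "Pons",
}


def canonical_tracer(name: str) -> str:
    if name in TRACERS:
        return name
    key = name.lower()
    if key in TRACER_ALIASES:
        return TRACER_ALIASES[key]
    for t in TRACERS:
        if key == t.lower():
            return t
    raise ValueError(f"unknown tracer {name!r}; known: {TRACERS}")


def canonical_reference(name: str) -> str:
    key = name.lower()
    if key in REFERENCE_ALIASES:
        return REFERENCE_ALIASES[key]
    raise ValueError(
        f"unknown reference {name!r}; known: {tuple(REFERENCE_ALIASES.values())}"
    )


class NoConversionError(KeyError):
    """Raised for (tracer, reference) pairs with no published SUVR->CL map."""


@dataclass(frozen=True)
class TracerCalibration:
    tracer: str
    reference: str
    intercept: float  # CL units
    slope: float      # CL per SUVR

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def to_cl(self, suvr: float) -> float:
        return self.intercept + self.slope * suvr

    def to_suvr(self, cl: float) -> float:
        return (cl - self.intercept) / self.slope


class CalibrationTable:
    """Published linear SUVR->CL coefficients, keyed by (tracer, reference)."""

    def __init__(self, entries: dict[tuple[str, str], TracerCalibration]):
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._entries)

    def get(self, tracer: str, reference: str) -> TracerCalibration:
        tracer = canonical_tracer(tracer)
        reference = canonical_reference(reference)
        try:
            return self._entries[(tracer, reference)]
        except KeyError:
            raise NoConversionError(
                f"no published conversion for tracer {tracer!r} "
                f"with reference {reference!r}"
            ) from None

    def has(self, tracer: str, reference: str) -> bool:
        try:
            self.get(tracer, reference)
            return True
        except (NoConversionError, ValueError):
            return False


def load_calibration_table(path: str | Path | None = None) -> CalibrationTable:
    """Load calibration coefficients from CSV (tracer,reference,intercept,slope).

    With no argument the packaged default table is used.
    """
    if path is None:
        src = resources.files("amypet").joinpath("data/calibration.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    entries = {}
    for row in df.itertuples(index=False):
        cal = TracerCalibration(
            tracer=canonical_tracer(row.tracer),
            reference=canonical_reference(row.reference),
            intercept=float(row.intercept),
            slope=float(row.slope),
        )
        entries[(cal.tracer, cal.reference)] = cal
    return CalibrationTable(entries)


_DEFAULT_TABLE: CalibrationTable | None = None


def default_calibration_table() -> CalibrationTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_calibration_table()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class SUVRResult:
    suvr: float
    target_name: str
    reference_name: str
    target_mean: float
    reference_mean: float


@dataclass(frozen=True)
class CentiloidResult:
    cl: float
    suvr: float
    calibration: TracerCalibration


@dataclass(frozen=True)
class ValidationResult:
    slope: float
    intercept: float
    r2: float
    n: int

    @property
    def pass_slope(self) -> bool:
        return 0.98 <= self.slope <= 1.02

    @property
    def pass_intercept(self) -> bool:
        return -2.0 <= self.intercept <= 2.0

    @property
    def pass_r2(self) -> bool:
        return self.r2 > 0.98

    @property
    def pass_all(self) -> bool:
        return self.pass_slope and self.pass_intercept and self.pass_r2


def compute_suvr(pet_std: Volume, vs: VOISet, reference: str) -> SUVRResult:
    """SUVR of the standardized PET: mean over the global target VOI divided
    by the mean over the chosen reference VOI."""
    reference = canonical_reference(reference)
    ref_mask = vs.reference_masks[reference]
    t_mean = mask_mean(pet_std, vs.target_mask)
    r_mean = mask_mean(pet_std, ref_mask)
    if r_mean <= 0:
        raise ValueError(
            f"non-positive reference mean ({r_mean:g}) in {reference!r}: "
            "upstream normalization or masking failed"
        )
    return SUVRResult(
        suvr=t_mean / r_mean,
        target_name=TARGET_NAME,
        reference_name=reference,
        target_mean=t_mean,
        reference_mean=r_mean,
    )


def suvr_to_centiloid(
    suvr: float,
    tracer: str,
    reference: str,
    table: CalibrationTable | None = None,
) -> CentiloidResult:
    """Convert an SUVR to the Centiloid scale with the published coefficients.

    Raises :class:`NoConversionError` for pairs without a published
    conversion. Individual CL values may legitimately fall outside
    [0, 100].
    """
    table = table or default_calibration_table()
    cal = table.get(tracer, reference)
    return CentiloidResult(cl=cal.to_cl(suvr), suvr=float(suvr), calibration=cal)


def validate_against_reference(
    pairs: list[tuple[float, float]]
) -> ValidationResult:
    """Klunk-style validation: OLS of computed CL on reference CL.

    The regression is computed = intercept + slope * reference (axes in
    that order, matching how replications of published CL values are
    assessed); R^2 is the squared Pearson correlation. Pass bands:
    slope in [0.98, 1.02], |intercept| <= 2 CL, R^2 > 0.98.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (computed, reference) pairs")
    computed, reference = arr[:, 0], arr[:, 1]
    if np.ptp(reference) == 0:
        raise ValueError("reference values are all equal; regression degenerate")
    res = sps.linregress(reference, computed)
    return ValidationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        n=arr.shape[0],
    )
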