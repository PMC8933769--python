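"""VOI (volume-of-interest) sets: reference regions, global target, subregions.

A :class:`VOISet` bundles the masks the Centiloid workflow needs:

* four reference regions used for count normalization — whole cerebellum
  (``WhlCbl``), cerebellar gray matter (``CerebGry``), pons (``Pons``) and
  whole cerebellum plus brainstem (``WhlCblBrnStm``);
* the global cortical + striatal target (``ctx``);
* five reporting subregions of the target: posterior cingulate gyrus plus
  precuneus, frontal, temporal, parietal cortex, and striatum.

All masks must live on one grid; the five subregions must be pairwise
disjoint and contained in the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .volumes import Grid3D, Mask, Volume, read_mask, write_mask

__all__ = [
    "REFERENCE_NAMES",
    "REGION_NAMES",
    "TARGET_NAME",
    "VOISet",
    "load_voi_set",
    "voi_set_from_dir",
    "save_voi_set",
    "mask_mean",
    "partition_report",
]

REFERENCE_NAMES = ("WhlCbl", "CerebGry", "Pons", "WhlCblBrnStm")
TARGET_NAME = "ctx"
REGION_NAMES = ("pcc_precuneus", "frontal", "temporal", "parietal", "striatum")


@dataclass
class VOISet:
    reference_masks: dict[str, Mask]
    target_mask: Mask
    region_masks: dict[str, Mask]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def grid(self) -> Grid3D:
        return self.target_mask.grid

    def validate(self) -> None:
        missing = set(REFERENCE_NAMES) - set(self.reference_masks)
        if missing:
            raise ValueError(f"missing reference masks: {sorted(missing)}")
        missing = set(REGION_NAMES) - set(self.region_masks)
        if missing:
            raise ValueError(f"missing region masks: {sorted(missing)}")

        grid = self.target_mask.grid
        for name, m in self._all_masks().items():
            if not m.grid.matches(grid):
                raise ValueError(f"mask {name!r} is not on the shared grid")
            if m.n_voxels == 0:
                raise ValueError(f"empty mask: {name!r}")

        names = list(REGION_NAMES)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = int(
                    (self.region_masks[a].data & self.region_masks[b].data).sum()
                )
                if overlap:
                    raise ValueError(
                        f"region masks {a!r} and {b!r} overlap in {overlap} voxels"
                    )
        tgt = self.target_mask.data
        for name in names:
            outside = int((self.region_masks[name].data & ~tgt).sum())
            if outside:
                raise ValueError(
                    f"region {name!r} has {outside} voxels outside the target mask"
                )

    def _all_masks(self) -> dict[str, Mask]:
        out = dict(self.reference_masks)
        out[TARGET_NAME] = self.target_mask
        out.update(self.region_masks)
        return out


def load_voi_set(paths: Mapping[str, str | Path], threshold: float = 0.5) -> VOISet:
    """Load a VOI set from a name -> NIfTI-path mapping.

    Files are binarized at ``> threshold`` (some template distributions
    have probabilistic edges). All VOISet invariants are enforced at load
    time so downstream code never sees an inconsistent set.
    """
    required = set(REFERENCE_NAMES) | {TARGET_NAME} | set(REGION_NAMES)
    missing = required - set(paths)
    if missing:
        raise ValueError(f"missing VOI paths for: {sorted(missing)}")
    masks = {name: read_mask(paths[name], name=name, threshold=threshold)
             for name in required}
    return VOISet(
        reference_masks={n: masks[n] for n in REFERENCE_NAMES},
        target_mask=masks[TARGET_NAME],
        region_masks={n: masks[n] for n in REGION_NAMES},
    )


def _canonical_filename(name: str) -> str:
    return f"voi_{name}_2mm.nii.gz"


def voi_set_from_dir(voi_dir: str | Path, threshold: float = 0.5) -> VOISet:
    """Load a VOI set from a directory of canonically named files
    (``voi_WhlCbl_2mm.nii.gz``, ``voi_ctx_2mm.nii.gz``, ...)."""
    voi_dir = Path(voi_dir)
    names = list(REFERENCE_NAMES) + [TARGET_NAME] + list(REGION_NAMES)
    paths = {}
    for name in names:
        for cand in (_canonical_filename(name), f"voi_{name}_2mm.nii"):
            p = voi_dir / cand
            if p.exists():
                paths[name] = p
                break
        else:
            raise FileNotFoundError(
                f"no VOI file for {name!r} in {voi_dir} "
                f"(expected {_canonical_filename(name)})"
            )
    return load_voi_set(paths, threshold=threshold)


def save_voi_set(vs: VOISet, voi_dir: str | Path) -> dict[str, Path]:
    """Write every mask of the set under canonical filenames; returns paths."""
    voi_dir = Path(voi_dir)
    voi_dir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, m in vs._all_masks().items():
        p = voi_dir / _canonical_filename(name)
        write_mask(m, p)
        out[name] = p
    return out


def mask_mean(v: Volume, m: Mask) -> float:
    """Unweighted arithmetic mean of ``v`` over the mask's voxels.

    This is the primitive behind every SUVR: mean target count over mean
    reference count.
    """
    if not v.grid.matches(m.grid):
        raise ValueError(f"volume grid does not match mask {m.name!r} grid")
    if m.n_voxels == 0:
        raise ValueError(f"empty mask: {m.name!r}")
    return float(v.data[m.data].mean())


def partition_report(vs: VOISet) -> pd.DataFrame:
    """Tabulate voxel counts and volumes (cc) for every mask in the set."""
    rows = []
    for kind, masks in (
        ("reference", vs.reference_masks),
        ("target", {TARGET_NAME: vs.target_mask}),
        ("region", vs.region_masks),
    ):
        for name, m in masks.items():
            rows.append(
                {"name": name, "kind": kind, "voxels": m.n_voxels,
                 "volume_cc": m.volume_cc}
            )
    return pd.DataFrame(rows)
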