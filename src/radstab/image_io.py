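"""Reading, writing and validating co-registered parametric maps and ROI labelmaps.

The analysis assumes all nine parametric maps (ADC, nCBV, nCBF, MTT, TTP,
CTH, COV, OEF, CMRO2) and the ROI labelmap live on one shared voxel grid;
this module enforces that contract and refuses misaligned inputs rather
than resampling (registration happens upstream, and silent resampling
hides errors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import schema

__all__ = [
    "ParametricMapSet",
    "RoiLabelmap",
    "read_map_set",
    "read_labelmap",
    "write_map_set",
    "write_labelmap",
]

VALID_LABELS = frozenset(
    {schema.LABEL_BACKGROUND, schema.LABEL_CET, schema.LABEL_NEL, schema.LABEL_NECROSIS}
)


class GridMismatchError(ValueError):
    """Maps or labelmap do not share one voxel grid."""


class LabelError(ValueError):
    """Labelmap contains values outside {0: background, 1: CET, 2: NEL, 3: necrosis}."""


class EmptyRoiError(ValueError):
    """Neither CET nor NEL contains any voxel."""


@dataclass
class ParametricMapSet:
    """Nine named 3D scalar maps on one voxel grid."""

    maps: dict[str, np.ndarray]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        missing = [m for m in schema.MAP_NAMES if m not in self.maps]
        if missing:
            raise KeyError(f"missing parametric maps: {missing}")
        extra = [m for m in self.maps if m not in schema.MAP_NAMES]
        if extra:
            raise KeyError(f"unknown map names: {extra}")
        shapes = {m: self.maps[m].shape for m in schema.MAP_NAMES}
        ref = shapes[schema.MAP_NAMES[0]]
        bad = {m: s for m, s in shapes.items() if s != ref}
        if bad:
            raise GridMismatchError(
                f"maps not on one grid: reference shape {ref}, mismatched {bad}"
            )
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.maps[schema.MAP_NAMES[0]].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing in mm, from the affine."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))


@dataclass
class RoiLabelmap:
    """Integer labelmap: 0 background, 1 CET, 2 NEL, 3 necrosis."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise LabelError("labelmap contains non-integer values")
            self.labels = rounded.astype(np.int16)
        present = set(np.unique(self.labels).tolist())
        bad = present - VALID_LABELS
        if bad:
            raise LabelError(f"labels outside {{0,1,2,3}} found: {sorted(bad)}")
        if schema.LABEL_CET not in present and schema.LABEL_NEL not in present:
            raise EmptyRoiError("labelmap has neither CET nor NEL voxels")
        self.affine = np.asarray(self.affine, dtype=float)

    def mask(self, roi: str) -> np.ndarray:
        return self.labels == schema.ROI_LABELS[roi]

    def voxel_counts(self) -> dict[str, int]:
        return {
            "background": int((self.labels == schema.LABEL_BACKGROUND).sum()),
            "CET": int((self.labels == schema.LABEL_CET).sum()),
            "NEL": int((self.labels == schema.LABEL_NEL).sum()),
            "necrosis": int((self.labels == schema.LABEL_NECROSIS).sum()),
        }


def read_map_set(paths: dict[str, str | Path]) -> ParametricMapSet:
    """Read the nine NIfTI parametric maps and validate the shared grid.

    ``paths`` maps each of the nine canonical map names to a ``.nii``/
    ``.nii.gz`` file.  Raises ``KeyError`` listing missing names and
    :class:`GridMismatchError` naming mismatched shapes or affines.
    """
    missing = [m for m in schema.MAP_NAMES if m not in paths]
    if missing:
        raise KeyError(f"missing parametric maps: {missing}")
    imgs = {m: nib.load(str(paths[m])) for m in schema.MAP_NAMES}
    ref_name = schema.MAP_NAMES[0]
    ref_affine = imgs[ref_name].affine
    for m, img in imgs.items():
        if not np.allclose(img.affine, ref_affine, atol=1e-5):
            raise GridMismatchError(
                f"map {m!r} affine differs from {ref_name!r}; inputs must be co-registered"
            )
    maps = {m: np.asarray(img.get_fdata(), dtype=np.float64) for m, img in imgs.items()}
    return ParametricMapSet(maps=maps, affine=np.asarray(ref_affine, dtype=float))


def read_labelmap(path: str | Path, map_set: ParametricMapSet) -> RoiLabelmap:
    """Read the ROI labelmap and validate it against ``map_set``'s grid."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.shape != map_set.shape:
        raise GridMismatchError(
            f"labelmap shape {data.shape} does not match map grid {map_set.shape}"
        )
    if not np.allclose(img.affine, map_set.affine, atol=1e-5):
        raise GridMismatchError("labelmap affine does not match the map set")
    return RoiLabelmap(labels=data, affine=map_set.affine)


def write_map_set(map_set: ParametricMapSet, directory: str | Path,
                  prefix: str = "") -> dict[str, Path]:
    """Write one NIfTI per map; returns the path mapping (a manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for m in schema.MAP_NAMES:
        p = directory / f"{prefix}{m}.nii.gz"
        nib.save(nib.Nifti1Image(map_set.maps[m].astype(np.float32), map_set.affine), str(p))
        out[m] = p
    return out


def write_labelmap(rois: RoiLabelmap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(rois.labels.astype(np.int16), rois.affine), str(path))
    return path


def write_manifest(entries: dict, path: str | Path) -> None:
    """Manifest: ``{patient: {timepoint: {"maps": {...}, "labelmap": path}}}``."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1, default=str)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
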