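"""Assemble the 1720-feature radiomics vector per patient-timepoint.

The vector always has exactly the 1720 schema names in canonical order.
Features that cannot be computed (empty CET or NEL) are set to NaN and
listed in a structured missingness report — never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .firstorder import first_order_features
from .heterogeneity import het_features
from .image_io import ParametricMapSet, RoiLabelmap
from .shape import shape_features
from .texture import DiscretizationPolicy, texture_features

__all__ = ["ExtractionReport", "extract_all", "extract_cohort"]


@dataclass
class ExtractionReport:
    """What was and was not computable for one patient-timepoint."""

    n_features: int
    missing: list[str] = field(default_factory=list)
    empty_rois: list[str] = field(default_factory=list)
    degenerate_shape_rois: list[str] = field(default_factory=list)
    voxel_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_missing(self) -> int:
        return len(self.missing)


def _roi_block(values: np.ndarray, mask: np.ndarray, roi: str, map_name: str,
               policy: DiscretizationPolicy, voxel_volume: float) -> dict[str, float]:
    out: dict[str, float] = {}
    fo = first_order_features(values[mask], n_bins=policy.n_bins, voxel_volume=voxel_volume)
    out.update({f"{roi}_{map_name}_firstorder_{k}": v for k, v in fo.items()})
    tx = texture_features(values, mask, policy)
    out.update({f"{roi}_{map_name}_{k}": v for k, v in tx.items()})
    return out


def extract_all(
    map_set: ParametricMapSet,
    rois: RoiLabelmap,
    policy: DiscretizationPolicy = DiscretizationPolicy(),
    het_bins: int = 64,
) -> tuple[pd.Series, ExtractionReport]:
    """Compute the full feature vector for one co-registered case.

    Returns a Series over the canonical 1720 names plus a report of
    missing entries.  An empty CET or NEL yields NaN for that ROI's
    93x9 intensity/texture features, its 14 shape features, and (since
    both ROIs are needed) the 18 heterogeneity features.
    """
    if map_set.shape != rois.labels.shape:
        raise ValueError(
            f"labelmap grid {rois.labels.shape} does not match maps {map_set.shape}"
        )
    names = schema.all_feature_names()
    values: dict[str, float] = {}
    report = ExtractionReport(n_features=len(names), voxel_counts=rois.voxel_counts())
    voxel_volume = float(np.prod(map_set.spacing))

    masks = {roi: rois.mask(roi) for roi in schema.ROI_NAMES}
    for roi, mask in masks.items():
        if not mask.any():
            report.empty_rois.append(roi)
            continue
        for map_name in schema.MAP_NAMES:
            arr = map_set.maps[map_name]
            if not np.all(np.isfinite(arr[mask])):
                raise ValueError(f"non-finite values inside {roi} on map {map_name}")
            values.update(_roi_block(arr, mask, roi, map_name, policy, voxel_volume))
        shp, meta = shape_features(mask, map_set.spacing)
        if meta["degenerate"]:
            report.degenerate_shape_rois.append(roi)
        values.update({f"{roi}_shape_{k}": v for k, v in shp.items()})

    values.update(het_features(map_set, rois, n_bins=het_bins))

    vec = pd.Series({n: values.get(n, np.nan) for n in names}, name="features")
    vec = vec.reindex(names)
    report.missing = vec.index[vec.isna()].tolist()
    return vec, report


def extract_cohort(
    cases: dict[str, tuple[ParametricMapSet, RoiLabelmap]],
    policy: DiscretizationPolicy = DiscretizationPolicy(),
    het_bins: int = 64,
) -> tuple[pd.DataFrame, dict[str, ExtractionReport]]:
    """Feature table (patients x 1720) for a mapping of case id -> inputs."""
    rows = {}
    reports = {}
    for case_id, (map_set, rois) in cases.items():
        vec, rep = extract_all(map_set, rois, policy=policy, het_bins=het_bins)
        rows[case_id] = vec
        reports[case_id] = rep
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient"
    return table, reports
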