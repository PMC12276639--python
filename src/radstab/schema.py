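"""Feature-name schema for the 1720-feature radiomics vector.

The vector decomposes as

    93 intensity/texture features x 9 parametric maps x 2 ROIs   = 1674
  + 14 shape features x 2 ROIs                                   =   28
  +  2 spatial-heterogeneity metrics x 9 maps                    =   18
                                                                  ------
                                                                   1720

Names follow ``<roi>_<map>_<family>_<feature>`` for intensity/texture,
``<roi>_shape_<feature>`` for shape and ``het_<map>_<metric>`` for the
CET-vs-NEL histogram-overlap metrics.  The ordering returned by
:func:`all_feature_names` is the canonical column order of every feature
table written by this package.
"""

from __future__ import annotations

MAP_NAMES: tuple[str, ...] = (
    "ADC", "nCBV", "nCBF", "MTT", "TTP", "CTH", "COV", "OEF", "CMRO2",
)

ROI_NAMES: tuple[str, ...] = ("CET", "NEL")

# label values in the ROI labelmap
LABEL_BACKGROUND = 0
LABEL_CET = 1
LABEL_NEL = 2
LABEL_NECROSIS = 3
ROI_LABELS: dict[str, int] = {"CET": LABEL_CET, "NEL": LABEL_NEL}

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

GLCM_NAMES: tuple[str, ...] = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)

GLRLM_NAMES: tuple[str, ...] = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES: tuple[str, ...] = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES: tuple[str, ...] = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES: tuple[str, ...] = (
    "Coarseness", "Contrast", "Busyness", "Complexity", "Strength",
)

SHAPE_NAMES: tuple[str, ...] = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow",
    "MajorAxisLength", "MinorAxisLength", "LeastAxisLength",
    "Elongation", "Flatness",
)

HET_METRIC_NAMES: tuple[str, ...] = ("intersection", "bhattacharyya")

TEXTURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

INTENSITY_FAMILIES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRST_ORDER_NAMES,
    **TEXTURE_FAMILIES,
}

# 18 + 24 + 16 + 16 + 14 + 5 = 93 per ROI-map block
N_PER_ROI_MAP = sum(len(v) for v in INTENSITY_FAMILIES.values())
N_FEATURES_TOTAL = (
    N_PER_ROI_MAP * len(MAP_NAMES) * len(ROI_NAMES)
    + len(SHAPE_NAMES) * len(ROI_NAMES)
    + len(HET_METRIC_NAMES) * len(MAP_NAMES)
)


def roi_map_feature_names(roi: str, map_name: str) -> list[str]:
    """The 93 intensity/texture names for one ROI on one parametric map."""
    return [
        f"{roi}_{map_name}_{family}_{feat}"
        for family, feats in INTENSITY_FAMILIES.items()
        for feat in feats
    ]


def shape_feature_names(roi: str) -> list[str]:
    return [f"{roi}_shape_{feat}" for feat in SHAPE_NAMES]


def het_feature_names() -> list[str]:
    return [
        f"het_{map_name}_{metric}"
        for map_name in MAP_NAMES
        for metric in HET_METRIC_NAMES
    ]


def all_feature_names() -> list[str]:
    """Canonical ordering of the full 1720-entry feature vector."""
    names: list[str] = []
    for roi in ROI_NAMES:
        for map_name in MAP_NAMES:
            names.extend(roi_map_feature_names(roi, map_name))
    for roi in ROI_NAMES:
        names.extend(shape_feature_names(roi))
    names.extend(het_feature_names())
    return names


def feature_family(name: str) -> str:
    """Family of a schema feature name (firstorder/glcm/.../shape/het)."""
    if name.startswith("het_"):
        return "het"
    parts = name.split("_")
    if len(parts) >= 3 and parts[1] == "shape":
        return "shape"
    return parts[2]


def write_schema_json(path) -> None:
    """Dump the pinned feature dictionary (names + family membership)."""
    import json

    payload = {
        "n_features": N_FEATURES_TOTAL,
        "maps": list(MAP_NAMES),
        "rois": list(ROI_NAMES),
        "families": {k: list(v) for k, v in INTENSITY_FAMILIES.items()},
        "shape": list(SHAPE_NAMES),
        "heterogeneity": list(HET_METRIC_NAMES),
        "feature_names": all_feature_names(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
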