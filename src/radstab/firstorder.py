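"""First-order (intensity-distribution) features of an ROI.

The 18 features summarise the marginal voxel-intensity distribution
inside one ROI on one parametric map.  Entropy and uniformity are
computed on a fixed-bin-count discretization of the ROI's own min-max
range; all moments use the population convention (divide by N).

Degenerate-ROI conventions: a constant ROI has variance 0, entropy 0,
uniformity 1, and skewness/kurtosis defined as 0 so that constant
phantoms propagate finite values instead of NaN.
"""

from __future__ import annotations

import numpy as np

from .schema import FIRST_ORDER_NAMES

__all__ = ["first_order_features"]


def _discretize_probabilities(v: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return np.array([1.0])
    counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
    counts = counts[counts > 0]
    return counts / counts.sum()


def first_order_features(values, n_bins: int = 32, voxel_volume: float = 1.0) -> dict[str, float]:
    """The 18 first-order features of the ROI intensity sample.

    Parameters
    ----------
    values
        Voxel intensities inside the ROI (any shape; flattened).
    n_bins
        Fixed bin count for the discretized entropy/uniformity.
    voxel_volume
        Physical voxel volume in mm^3; only TotalEnergy uses it.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty ROI: no voxels to summarise")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite intensity values in ROI")

    n = v.size
    mean = float(v.mean())
    var = float(v.var())  # population
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    probs = _discretize_probabilities(v, n_bins)

    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean((v - mean) ** 3) / sd**3)
        kurt = float(np.mean((v - mean) ** 4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0

    out = {
        "Energy": float(np.sum(v**2)),
        "TotalEnergy": float(voxel_volume * np.sum(v**2)),
        "Entropy": float(-(probs * np.log2(probs)).sum()),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(v**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((probs**2).sum()),
    }
    assert tuple(out) == FIRST_ORDER_NAMES
    return out
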