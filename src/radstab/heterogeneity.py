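"""CET-vs-NEL spatial heterogeneity via histogram overlap.

Two metrics compare the voxel-intensity histograms of the
contrast-enhancing tumor (CET, ``H1``) and the non-enhancing lesion
(NEL, ``H2``) on each parametric map:

* histogram intersection ``sum_i min(H1_i, H2_i)`` — 1 for identical
  unit-sum histograms, 0 for disjoint supports;
* Bhattacharyya distance in its bounded form
  ``sqrt(1 - sum_i sqrt(H1_i * H2_i))`` — 0 for identical histograms,
  1 for disjoint supports.

Histograms are built on shared bin edges spanning the pooled CET∪NEL
intensity range so that both ROIs are binned identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import schema

__all__ = [
    "Histogram",
    "HeterogeneityResult",
    "build_histogram",
    "intersection",
    "bhattacharyya",
    "het_features",
]

DEFAULT_N_BINS = 64


@dataclass(frozen=True)
class Histogram:
    """Unit-sum binned distribution with explicit bin edges."""

    probabilities: np.ndarray
    edges: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        e = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "edges", e)
        if p.ndim != 1 or e.ndim != 1 or e.size != p.size + 1:
            raise ValueError("edges must have len(probabilities) + 1 entries")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        if np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing")


@dataclass(frozen=True)
class HeterogeneityResult:
    intersection: float
    bhattacharyya: float
    n_bins: int
    pooled_range: tuple[float, float]


def build_histogram(values, n_bins: int, range: tuple[float, float] | None = None) -> Histogram:
    """Bin ``values`` into a unit-sum histogram.

    All bins are half-open ``[lo, hi)`` except the last, which is closed;
    values outside ``range`` are clipped into the end bins.  A degenerate
    range (``min == max``, e.g. a constant ROI) yields a single bin
    carrying mass 1.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot build a histogram from an empty ROI")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite intensity values in ROI")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if range is None:
        lo, hi = float(v.min()), float(v.max())
    else:
        lo, hi = float(range[0]), float(range[1])
        if lo > hi:
            raise ValueError("range.min must not exceed range.max")
    if lo == hi:
        # degenerate range: all mass in one bin
        return Histogram(np.array([1.0]), np.array([lo, lo + 1.0]))
    v = np.clip(v, lo, hi)
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    return Histogram(counts / counts.sum(), edges)


def _check_aligned(h1: Histogram, h2: Histogram) -> None:
    if h1.edges.size != h2.edges.size or not np.allclose(h1.edges, h2.edges):
        raise ValueError(
            "histograms are binned on different edges; rebuild both on a "
            "shared (pooled-range) grid before comparing"
        )


def intersection(h1: Histogram, h2: Histogram) -> float:
    """Histogram intersection ``sum_i min(H1_i, H2_i)`` in [0, 1]."""
    _check_aligned(h1, h2)
    return float(np.minimum(h1.probabilities, h2.probabilities).sum())


def bhattacharyya(h1: Histogram, h2: Histogram) -> float:
    """Bounded Bhattacharyya distance ``sqrt(1 - BC)`` in [0, 1].

    ``BC = sum_i sqrt(H1_i * H2_i)`` is the Bhattacharyya coefficient;
    the bounded form maps identical histograms to 0 and disjoint
    supports to 1.
    """
    _check_aligned(h1, h2)
    bc = float(np.sqrt(h1.probabilities * h2.probabilities).sum())
    gap = max(0.0, 1.0 - min(bc, 1.0))
    if gap < 1e-12:  # identical up to float rounding of the unit sum
        return 0.0
    return float(np.sqrt(gap))


def compare_rois(cet_values, nel_values, n_bins: int = DEFAULT_N_BINS) -> HeterogeneityResult:
    """Both overlap metrics for one map, binned over the pooled range."""
    cet = np.asarray(cet_values, dtype=float).ravel()
    nel = np.asarray(nel_values, dtype=float).ravel()
    if cet.size == 0 or nel.size == 0:
        raise ValueError("CET and NEL must both be non-empty")
    pooled = np.concatenate([cet, nel])
    lo, hi = float(pooled.min()), float(pooled.max())
    h1 = build_histogram(cet, n_bins, (lo, hi))
    h2 = build_histogram(nel, n_bins, (lo, hi))
    return HeterogeneityResult(
        intersection=intersection(h1, h2),
        bhattacharyya=bhattacharyya(h1, h2),
        n_bins=len(h1.probabilities),
        pooled_range=(lo, hi),
    )


def het_features(map_set, rois, n_bins: int = DEFAULT_N_BINS) -> dict[str, float]:
    """The 18 heterogeneity features (9 maps x 2 metrics).

    Missing when either ROI is empty: every value is NaN (callers get a
    structured report from :func:`radstab.extract.extract_all`).
    """
    cet_mask = rois.labels == schema.LABEL_CET
    nel_mask = rois.labels == schema.LABEL_NEL
    out: dict[str, float] = {}
    both_present = bool(cet_mask.any() and nel_mask.any())
    for map_name in schema.MAP_NAMES:
        arr = map_set.maps[map_name]
        if both_present:
            res = compare_rois(arr[cet_mask], arr[nel_mask], n_bins=n_bins)
            out[f"het_{map_name}_intersection"] = res.intersection
            out[f"het_{map_name}_bhattacharyya"] = res.bhattacharyya
        else:
            out[f"het_{map_name}_intersection"] = float("nan")
            out[f"het_{map_name}_bhattacharyya"] = float("nan")
    return out
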