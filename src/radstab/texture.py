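"""3D texture features: GLCM, GLRLM, GLSZM, GLDM and NGTDM.

Intensities are discretized to a fixed bin count (default 32) over the
ROI's own min-max range, which is scale-free across maps with
heterogeneous units (ADC vs. normalized CBV).  Co-occurrence and
run-length matrices are built over the 13 unique 3D directions at
distance 1 and feature values are averaged over directions; the GLCM is
symmetric.  Zone, dependence and gray-tone-difference matrices use the
26-neighbourhood.

Degenerate inputs (single gray level) return the natural limits of each
feature (e.g. GLCM joint energy 1, contrast 0) instead of NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .schema import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
)

__all__ = ["DiscretizationPolicy", "discretize", "texture_features"]

_EPS = np.finfo(float).eps

# 13 unique direction vectors in 3D (one of each +/- pair, first
# nonzero component positive)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
)

_NEIGHBOUR_OFFSETS_26 = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


@dataclass(frozen=True)
class DiscretizationPolicy:
    """Fixed-bin-count gray-level discretization over the per-ROI range."""

    n_bins: int = 32

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def discretize(values: np.ndarray, mask: np.ndarray, policy: DiscretizationPolicy) -> np.ndarray:
    """Map ROI intensities to gray levels 1..n_bins (0 outside the mask)."""
    levels = np.zeros(values.shape, dtype=np.int32)
    v = values[mask]
    if v.size == 0:
        return levels
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        levels[mask] = 1
        return levels
    lv = np.floor((v - lo) / (hi - lo) * policy.n_bins).astype(np.int32) + 1
    levels[mask] = np.clip(lv, 1, policy.n_bins)
    return levels


def _shift_pairs(levels: np.ndarray, offset: tuple[int, int, int]):
    """Index pairs of in-mask voxels separated by ``offset``."""
    sl_src, sl_dst = [], []
    for o in offset:
        if o >= 0:
            sl_src.append(slice(None, levels.shape[len(sl_src)] - o or None))
            sl_dst.append(slice(o, None))
        else:
            sl_src.append(slice(-o, None))
            sl_dst.append(slice(None, o))
    a = levels[tuple(sl_src)]
    b = levels[tuple(sl_dst)]
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


# ---------------------------------------------------------------- GLCM


def _glcm_matrix(levels: np.ndarray, n_levels: int, offset) -> np.ndarray:
    a, b = _shift_pairs(levels, offset)
    if a.size == 0:
        return np.zeros((n_levels, n_levels))
    idx = (a - 1) * n_levels + (b - 1)
    counts = np.bincount(idx, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    return (counts + counts.T).astype(float)  # symmetric


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    if total == 0:
        return {k: float("nan") for k in GLCM_NAMES}
    # restrict to gray levels present in the matrix
    present = P.sum(axis=1) > 0
    p = P[np.ix_(present, present)] / total
    g = (np.nonzero(present)[0] + 1).astype(float)
    ng = g.size
    i = g[:, None]
    j = g[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((g * px).sum())
    muy = float((g * py).sum())
    sigx = float(np.sqrt(((g - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((g - muy) ** 2 * py).sum()))

    k_sum = np.arange(2, 2 * int(g.max()) + 1)
    p_sum = np.array([p[(i + j) == k].sum() for k in k_sum])
    k_diff = np.arange(0, int(g.max()))
    p_diff = np.array([p[np.abs(i - j) == k].sum() for k in k_diff])

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hxy = ent(p)
    hx = ent(px)
    hy = ent(py)
    outer = px[:, None] * py[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-(p * np.log2(outer + _EPS)).sum())
        hxy2 = float(-(outer * np.log2(outer + _EPS)).sum())

    da = float((k_diff * p_diff).sum())
    corr = 1.0 if sigx * sigy == 0 else float(((i * j * p).sum() - mux * muy) / (sigx * sigy))
    imc1 = 0.0 if max(hx, hy) == 0 else float((hxy - hxy1) / max(hx, hy))
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: sqrt of second-largest eigenvalue of Q
    if ng < 2:
        mcc = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            Q = (p / px[:, None]) @ (p / py[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(np.clip(ev[1], 0.0, 1.0)))

    off_diag = np.abs(i - j) > 0
    return {
        "Autocorrelation": float((i * j * p).sum()),
        "JointAverage": mux,
        "ClusterProminence": float(((i + j - mux - muy) ** 4 * p).sum()),
        "ClusterShade": float(((i + j - mux - muy) ** 3 * p).sum()),
        "ClusterTendency": float(((i + j - mux - muy) ** 2 * p).sum()),
        "Contrast": float(((i - j) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((i - j) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(i - j))).sum()),
        "Idn": float((p / (1.0 + np.abs(i - j) / ng)).sum()),
        "InverseVariance": float((p[off_diag] / (i - j)[off_diag] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((i - mux) ** 2 * p).sum()),
        "MCC": mcc,
    }


# ------------------------------------------------- run/zone/dependence


def _distribution_stats(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Shared statistics of a (gray level x size) count matrix.

    Generic keys; families map them onto their own feature names.
    ``size`` is the run length, zone size or dependence size.
    """
    N = P.sum()
    if N == 0:
        return {}
    p = P / N
    g = np.arange(1, P.shape[0] + 1, dtype=float)
    r = np.arange(1, P.shape[1] + 1, dtype=float)
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    mug = float((g * pg).sum())
    mur = float((r * pr).sum())
    nz = p[p > 0]
    gi2 = g**2
    ri2 = r**2
    inv_g2 = 1.0 / gi2
    inv_r2 = 1.0 / ri2
    return {
        "SmallEmphasis": float((pr * inv_r2).sum()),
        "LargeEmphasis": float((pr * ri2).sum()),
        "GrayLevelNonUniformity": float(N * (pg**2).sum()),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "SizeNonUniformity": float(N * (pr**2).sum()),
        "SizeNonUniformityNormalized": float((pr**2).sum()),
        "Percentage": float(N / n_voxels),
        "GrayLevelVariance": float((pg * (g - mug) ** 2).sum()),
        "SizeVariance": float((pr * (r - mur) ** 2).sum()),
        "Entropy": float(-(nz * np.log2(nz)).sum()),
        "LowGrayLevelEmphasis": float((pg * inv_g2).sum()),
        "HighGrayLevelEmphasis": float((pg * gi2).sum()),
        "SmallLow": float((p * np.outer(inv_g2, inv_r2)).sum()),
        "SmallHigh": float((p * np.outer(gi2, inv_r2)).sum()),
        "LargeLow": float((p * np.outer(inv_g2, ri2)).sum()),
        "LargeHigh": float((p * np.outer(gi2, ri2)).sum()),
    }


_GLRLM_KEYMAP = dict(zip(GLRLM_NAMES, (
    "SmallEmphasis", "LargeEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeNonUniformity",
    "SizeNonUniformityNormalized", "Percentage", "GrayLevelVariance",
    "SizeVariance", "Entropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallLow", "SmallHigh", "LargeLow",
    "LargeHigh",
)))

_GLSZM_KEYMAP = dict(zip(GLSZM_NAMES, (
    "SmallEmphasis", "LargeEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeNonUniformity",
    "SizeNonUniformityNormalized", "Percentage", "GrayLevelVariance",
    "SizeVariance", "Entropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallLow", "SmallHigh", "LargeLow",
    "LargeHigh",
)))

_GLDM_KEYMAP = dict(zip(GLDM_NAMES, (
    "SmallEmphasis", "LargeEmphasis", "GrayLevelNonUniformity",
    "SizeNonUniformity", "SizeNonUniformityNormalized",
    "GrayLevelVariance", "SizeVariance", "Entropy",
    "LowGrayLevelEmphasis", "HighGrayLevelEmphasis", "SmallLow",
    "SmallHigh", "LargeLow", "LargeHigh",
)))


def _glrlm_matrix(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length counts along one direction.

    Voxels are sorted line-by-line; a run breaks when the line changes,
    the position along the line jumps, or the gray level changes.
    """
    coords = np.argwhere(levels > 0)
    lv = levels[levels > 0]
    d = np.asarray(direction)
    s = int(d @ d)  # step of the line parameter per voxel move
    t = coords @ d
    line_key = coords * s - t[:, None] * d  # constant along a line
    order = np.lexsort((t, line_key[:, 2], line_key[:, 1], line_key[:, 0]))
    t = t[order]
    key = line_key[order]
    lv_sorted = lv[order]
    same_line = np.all(key[1:] == key[:-1], axis=1)
    contiguous = (t[1:] - t[:-1]) == s
    same_level = lv_sorted[1:] == lv_sorted[:-1]
    new_run = np.concatenate(([True], ~(same_line & contiguous & same_level)))
    run_id = np.cumsum(new_run) - 1
    run_lengths = np.bincount(run_id)
    run_levels = lv_sorted[new_run]
    P = np.zeros((n_levels, int(run_lengths.max())))
    np.add.at(P, (run_levels - 1, run_lengths - 1), 1.0)
    return P


def _glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    structure = np.ones((3, 3, 3), dtype=int)
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for lvl in range(1, n_levels + 1):
        m = levels == lvl
        if not m.any():
            continue
        lab, n_zones = ndimage.label(m, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_by_level.append((lvl, sizes))
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((n_levels, max_size))
    for lvl, sizes in sizes_by_level:
        np.add.at(P, (lvl - 1, sizes - 1), 1.0)
    return P


def _gldm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts: neighbours (26-conn) with identical level (alpha=0)."""
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int32)
    for off in _NEIGHBOUR_OFFSETS_26:
        sl_src, sl_dst = [], []
        for axis, o in enumerate(off):
            if o >= 0:
                sl_src.append(slice(None, levels.shape[axis] - o or None))
                sl_dst.append(slice(o, None))
            else:
                sl_src.append(slice(-o, None))
                sl_dst.append(slice(None, o))
        a = levels[tuple(sl_src)]
        b = levels[tuple(sl_dst)]
        match = (a > 0) & (b > 0) & (a == b)
        dep[tuple(sl_src)] += match
    # dependence size = dependent neighbours + the voxel itself
    j = dep[mask] + 1
    lv = levels[mask]
    P = np.zeros((n_levels, int(j.max())))
    np.add.at(P, (lv - 1, j - 1), 1.0)
    return P


def _ngtdm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    mask = levels > 0
    vals = levels.astype(float)
    nb_sum = np.zeros(levels.shape)
    nb_cnt = np.zeros(levels.shape)
    for off in _NEIGHBOUR_OFFSETS_26:
        sl_src, sl_dst = [], []
        for axis, o in enumerate(off):
            if o >= 0:
                sl_src.append(slice(None, levels.shape[axis] - o or None))
                sl_dst.append(slice(o, None))
            else:
                sl_src.append(slice(-o, None))
                sl_dst.append(slice(None, o))
        src = tuple(sl_src)
        dst = tuple(sl_dst)
        valid = mask[dst]
        nb_sum[src] += np.where(valid, vals[dst], 0.0)
        nb_cnt[src] += valid

    use = mask & (nb_cnt > 0)
    n_vp = int(use.sum())
    if n_vp == 0:
        return {k: 0.0 for k in NGTDM_NAMES}
    lv = levels[use]
    diff = np.abs(vals[use] - nb_sum[use] / nb_cnt[use])
    s = np.zeros(n_levels)
    np.add.at(s, lv - 1, diff)
    n_i = np.bincount(lv - 1, minlength=n_levels).astype(float)
    p_i = n_i / n_vp
    present = p_i > 0
    gp = np.arange(1, n_levels + 1, dtype=float)[present]
    pp = p_i[present]
    sp = s[present]
    n_gp = int(present.sum())

    coarse_den = float((pp * sp).sum())
    coarseness = 1e6 if coarse_den == 0 else 1.0 / coarse_den
    if n_gp > 1:
        di = gp[:, None] - gp[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = float((pij * di**2).sum()) * sp.sum() / (n_gp * (n_gp - 1) * n_vp)
        busy_den = float(np.abs(gp[:, None] * pp[:, None] - gp[None, :] * pp[None, :]).sum())
        busyness = 0.0 if busy_den == 0 else coarse_den / busy_den
        psps = pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
        complexity = float((np.abs(di) * psps / (pp[:, None] + pp[None, :])).sum()) / n_vp
        strength_den = float(sp.sum())
        strength = (
            0.0
            if strength_den == 0
            else float(((pp[:, None] + pp[None, :]) * di**2).sum()) / strength_den
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


def texture_features(
    values: np.ndarray,
    mask: np.ndarray,
    policy: DiscretizationPolicy = DiscretizationPolicy(),
) -> dict[str, float]:
    """All 75 texture features of one ROI on one map.

    Returns keys ``"<family>_<Feature>"`` with family counts
    glcm 24, glrlm 16, glszm 16, gldm 14, ngtdm 5.
    """
    mask = np.asarray(mask).astype(bool)
    values = np.asarray(values, dtype=float)
    if int(mask.sum()) < 2:
        raise ValueError("texture features need an ROI of at least 2 voxels")
    if not np.all(np.isfinite(values[mask])):
        raise ValueError("non-finite intensity values in ROI")
    levels = discretize(values, mask, policy)
    ng = policy.n_bins
    n_vox = int(mask.sum())

    out: dict[str, float] = {}

    glcm_acc = {k: 0.0 for k in GLCM_NAMES}
    glrlm_acc = {k: 0.0 for k in GLRLM_NAMES}
    n_dir = len(DIRECTIONS_3D)
    for d in DIRECTIONS_3D:
        fg = _glcm_features(_glcm_matrix(levels, ng, d))
        fr = _distribution_stats(_glrlm_matrix(levels, ng, d), n_vox)
        for k in GLCM_NAMES:
            glcm_acc[k] += fg[k] / n_dir
        for k in GLRLM_NAMES:
            glrlm_acc[k] += fr[_GLRLM_KEYMAP[k]] / n_dir
    out.update({f"glcm_{k}": v for k, v in glcm_acc.items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_acc.items()})

    sz = _distribution_stats(_glszm_matrix(levels, ng), n_vox)
    out.update({f"glszm_{k}": sz[_GLSZM_KEYMAP[k]] for k in GLSZM_NAMES})

    dm = _distribution_stats(_gldm_matrix(levels, ng), n_vox)
    out.update({f"gldm_{k}": dm[_GLDM_KEYMAP[k]] for k in GLDM_NAMES})

    out.update({f"ngtdm_{k}": v for k, v in _ngtdm_features(levels, ng).items()})
    return out
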