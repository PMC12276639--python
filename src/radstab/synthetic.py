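"""Synthetic cohorts and phantoms with designed effects.

Two generators make every downstream stage testable without any image
download:

* :func:`simulate_feature_cohort` — feature-level cohorts with designed
  genotype effects (Gaussian marginals, class effect in the mean only,
  so the single-feature AUC has the closed form ``Phi(d/sqrt(2))``) and
  designed between-timepoint correlation (a bivariate-normal copula per
  feature, matching what the ICC stability filter estimates).
* :func:`simulate_phantom_pair` — small volume-level phantoms: three
  concentric ellipsoid shells (necrosis core, CET shell, NEL shell) on a
  shared grid, with per-map per-ROI means/SDs and spatially smooth
  Gaussian noise (white noise convolved with a Gaussian kernel).

:func:`simulate_study` builds the paired cross-sectional + longitudinal
design used by the best-vs-concordant model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import schema
from .image_io import ParametricMapSet, RoiLabelmap

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "PhantomConfig",
    "EllipsoidShells",
    "simulate_feature_cohort",
    "simulate_phantom_pair",
    "simulate_study",
]


class ConfigurationError(ValueError):
    """A cohort/phantom configuration field is invalid."""


class GeometryError(ValueError):
    """Phantom ROI geometry is overlapping or mis-ordered."""


# ------------------------------------------------------------ cohorts


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic feature-level cohort.

    ``effect_size`` is the standardized mean difference (Cohen's d) of
    each informative feature between genotype classes; within-class SD
    is 1.  ``stability_rho`` is the between-timepoint Pearson
    correlation assigned to stable features, ``unstable_fraction`` of
    the informative features get ``unstable_rho`` instead.  Class
    allocation is fixed-count: exactly ``round(n * prevalence)``
    positives.
    """

    n_patients: int = 312
    prevalence: float = 0.25
    n_features: int = 200
    n_informative: int = 10
    effect_size: float = 1.0
    feature_correlation: float = 0.0
    stability_rho: float = 0.95
    unstable_fraction: float = 0.0
    unstable_rho: float = 0.1
    paired: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 4:
            raise ConfigurationError("n_patients must be >= 4")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative must not exceed n_features")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ConfigurationError("feature_correlation must lie in [0, 1)")
        for name in ("stability_rho", "unstable_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.unstable_fraction <= 1.0:
            raise ConfigurationError("unstable_fraction must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """Feature tables plus ground truth of the generating design."""

    features_t1: pd.DataFrame
    labels: pd.Series
    features_t2: pd.DataFrame | None = None
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def informative_features(self) -> list[str]:
        return self.truth.index[self.truth["informative"]].tolist()


def _feature_names(n: int) -> list[str]:
    """Use the real radiomics schema names so cohorts match the pipeline."""
    pool = schema.all_feature_names()
    if n <= len(pool):
        return pool[:n]
    extra = [f"extra_feature_{i:04d}" for i in range(n - len(pool))]
    return pool + extra


def _fixed_count_labels(n: int, prevalence: float, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(n * prevalence))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    return y


def _sample_tables(
    n_patients: int,
    prevalence: float,
    names: list[str],
    d_t1: np.ndarray,
    d_t2: np.ndarray | None,
    rho: np.ndarray | None,
    feature_correlation: float,
    informative: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.Series]:
    """Core sampler.

    t1: ``x = d_t1 * y + e`` with unit within-class SD; informative
    features optionally share a latent factor giving within-block
    correlation ``feature_correlation``.  t2 (when requested):
    ``x2 = d_t2 * y + (rho * e1 + sqrt(1 - rho^2) * e2)`` — the noise is
    a bivariate-normal copula with correlation ``rho`` and the class
    effect at t2 is set explicitly by ``d_t2`` (callers decide how much
    of the genotype signal persists on the recurrence scan).
    """
    p = len(names)
    y = _fixed_count_labels(n_patients, prevalence, rng)
    e1 = rng.standard_normal((n_patients, p))
    if feature_correlation > 0 and informative.any():
        z = rng.standard_normal(n_patients)
        c = feature_correlation
        e1[:, informative] = (
            np.sqrt(c) * z[:, None]
            + np.sqrt(1 - c) * e1[:, informative]
        )
    x1 = d_t1[None, :] * y[:, None] + e1
    ids = [f"P{i:04d}" for i in range(n_patients)]
    t1 = pd.DataFrame(x1, index=ids, columns=names)
    t1.index.name = "patient"
    labels = pd.Series(y, index=ids, name="genotype")
    t2 = None
    if rho is not None:
        e2 = rng.standard_normal((n_patients, p))
        if feature_correlation > 0 and informative.any():
            z2 = rng.standard_normal(n_patients)
            c = feature_correlation
            e2[:, informative] = (
                np.sqrt(c) * z2[:, None]
                + np.sqrt(1 - c) * e2[:, informative]
            )
        noise2 = rho[None, :] * e1 + np.sqrt(1.0 - rho[None, :] ** 2) * e2
        x2 = (d_t2 if d_t2 is not None else d_t1)[None, :] * y[:, None] + noise2
        t2 = pd.DataFrame(x2, index=ids, columns=names)
        t2.index.name = "patient"
    return t1, t2, labels


def simulate_feature_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort of designed informative features.

    Informative features differ between classes by ``effect_size``
    within-class SDs; the rest are class-independent noise.  With
    ``paired=True`` each feature's (t1, t2) values follow a bivariate
    Gaussian whose correlation is the feature's assigned stability; the
    class effect at t2 is attenuated by the same factor, so unstable
    features lose their genotype signal on the recurrence scan.
    Identical config + seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    names = _feature_names(config.n_features)
    p = config.n_features

    informative = np.zeros(p, dtype=bool)
    idx = rng.choice(p, size=config.n_informative, replace=False)
    informative[idx] = True
    d = np.where(informative, config.effect_size, 0.0)

    rho = np.full(p, config.stability_rho)
    n_unstable = int(round(config.unstable_fraction * config.n_informative))
    if n_unstable:
        unstable_idx = idx[:n_unstable]
        rho[unstable_idx] = config.unstable_rho

    t1, t2, labels = _sample_tables(
        config.n_patients, config.prevalence, names,
        d_t1=d,
        d_t2=d * rho if config.paired else None,  # unstable features lose signal at t2
        rho=rho if config.paired else None,
        feature_correlation=config.feature_correlation,
        informative=informative,
        rng=rng,
    )
    truth = pd.DataFrame(
        {
            "informative": informative,
            "effect_size": d,
            "stability_rho": rho if config.paired else np.nan,
        },
        index=pd.Index(names, name="feature"),
    )
    return SyntheticCohort(features_t1=t1, features_t2=t2, labels=labels, truth=truth)


def simulate_study(
    scenario: str,
    seed: int,
    n_cross: int = 312,
    n_long: int = 38,
    prevalence: float = 0.25,
    n_features: int = 400,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Paired cross-sectional + longitudinal cohorts for model comparison.

    ``scenario="stable_signal"`` (IDH-like): 10 strong informative
    features (d = 2.0) are temporally unstable (rho = 0.1, signal gone
    on the recurrence scan) and 10 weaker ones (d = 1.2) are stable
    (rho = 0.95, signal persists).  All 20 share a latent factor, so the
    L1 selection — which keeps one of a correlated group — makes the
    unrestricted "best" model lean on the strong unstable features and
    degrade on recurrence scans, while the stability-filtered
    "concordant" model holds up.

    ``scenario="unstable_signal"`` (EGFR-like): the 10 cross-sectional
    informative features (d = 1.2, rho = 0.2) carry no class effect in
    the longitudinal cohort at all (the genotype-imaging association
    does not replicate), so both models collapse to chance there.
    """
    if scenario not in {"stable_signal", "unstable_signal"}:
        raise ConfigurationError(
            "scenario must be 'stable_signal' or 'unstable_signal'"
        )
    rng = np.random.default_rng(seed)
    names = _feature_names(n_features)
    p = n_features

    idx = rng.choice(p, size=20, replace=False)
    strong, weak = idx[:10], idx[10:]
    d_cross = np.zeros(p)
    d_long_t2 = np.zeros(p)
    rho = np.full(p, 0.8)  # uninformative features are moderately stable
    # the informative features share a latent factor (they read the same
    # biology), so the penalized selection keeps only a few of them
    informative_corr = 0.6
    if scenario == "stable_signal":
        d_cross[strong] = 2.0
        d_cross[weak] = 1.2
        rho[strong] = 0.1
        rho[weak] = 0.95
        d_long_t1 = d_cross.copy()
        d_long_t2[weak] = 1.2   # stable features keep their signal on recurrence
    else:
        d_cross[strong] = 1.2
        rho[strong] = 0.2
        d_long_t1 = np.zeros(p)  # association absent in the longitudinal cohort

    informative = d_cross != 0

    t1c, _, yc = _sample_tables(
        n_cross, prevalence, names, d_t1=d_cross, d_t2=None, rho=None,
        feature_correlation=informative_corr, informative=informative, rng=rng,
    )
    cross = SyntheticCohort(
        features_t1=t1c,
        labels=yc,
        truth=pd.DataFrame(
            {"informative": informative, "effect_size": d_cross, "stability_rho": rho},
            index=pd.Index(names, name="feature"),
        ),
    )

    t1l, t2l, yl = _sample_tables(
        n_long, prevalence, names, d_t1=d_long_t1, d_t2=d_long_t2, rho=rho,
        feature_correlation=informative_corr, informative=informative, rng=rng,
    )
    t1l.index = [f"L{i:04d}" for i in range(n_long)]
    t2l.index = t1l.index
    yl.index = t1l.index
    longitudinal = SyntheticCohort(
        features_t1=t1l,
        features_t2=t2l,
        labels=yl,
        truth=cross.truth,
    )
    return cross, longitudinal


# ------------------------------------------------------------ phantoms


@dataclass(frozen=True)
class EllipsoidShells:
    """Concentric ellipsoid shells: necrosis core, CET shell, NEL shell.

    Radii are per-axis semi-axes in voxels; strict nesting
    ``necrosis < cet < nel`` keeps the three ROIs pairwise disjoint.
    """

    center: tuple[float, float, float] = (23.5, 23.5, 23.5)
    necrosis_radii: tuple[float, float, float] = (6.0, 6.0, 6.0)
    cet_radii: tuple[float, float, float] = (12.0, 12.0, 12.0)
    nel_radii: tuple[float, float, float] = (19.0, 19.0, 19.0)

    def __post_init__(self):
        nec = np.asarray(self.necrosis_radii)
        cet = np.asarray(self.cet_radii)
        nel = np.asarray(self.nel_radii)
        if np.any(nec <= 0):
            raise GeometryError("necrosis radii must be positive")
        if not (np.all(nec < cet) and np.all(cet < nel)):
            raise GeometryError(
                "shells must be strictly nested (necrosis < cet < nel); "
                "overlapping ROI geometry is not representable"
            )


def _default_means() -> dict[str, dict[str, float]]:
    # plausible map values: ADC in 1e-3 mm^2/s, perfusion normalized to
    # normal-appearing white matter, times in seconds
    return {
        "ADC":   {"background": 0.80, "CET": 1.00, "NEL": 1.40, "necrosis": 2.20},
        "nCBV":  {"background": 1.00, "CET": 3.50, "NEL": 1.50, "necrosis": 0.50},
        "nCBF":  {"background": 1.00, "CET": 3.00, "NEL": 1.40, "necrosis": 0.50},
        "MTT":   {"background": 4.50, "CET": 5.50, "NEL": 5.00, "necrosis": 6.00},
        "TTP":   {"background": 16.0, "CET": 18.0, "NEL": 17.0, "necrosis": 20.0},
        "CTH":   {"background": 2.00, "CET": 3.50, "NEL": 2.80, "necrosis": 4.00},
        "COV":   {"background": 0.45, "CET": 0.65, "NEL": 0.55, "necrosis": 0.70},
        "OEF":   {"background": 0.30, "CET": 0.35, "NEL": 0.32, "necrosis": 0.25},
        "CMRO2": {"background": 1.40, "CET": 2.20, "NEL": 1.60, "necrosis": 0.80},
    }


def _default_sds() -> dict[str, dict[str, float]]:
    return {
        m: {roi: 0.15 * max(abs(v), 0.1) for roi, v in rois.items()}
        for m, rois in _default_means().items()
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Design of a small volume-level phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_geometry: EllipsoidShells = field(default_factory=EllipsoidShells)
    per_map_means: dict = field(default_factory=_default_means)
    per_map_sds: dict = field(default_factory=_default_sds)
    smoothness: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.grid_shape):
            raise ConfigurationError("grid_shape axes must be >= 8 voxels")
        if any(s > 96 for s in self.grid_shape):
            raise ConfigurationError("phantoms are desk-scale; grid axes must be <= 96")
        for m in schema.MAP_NAMES:
            if m not in self.per_map_means or m not in self.per_map_sds:
                raise ConfigurationError(f"per-map means/sds missing map {m!r}")
        if self.smoothness < 0:
            raise ConfigurationError("smoothness must be >= 0")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def _smooth_unit_noise(shape, smoothness, rng) -> np.ndarray:
    """White Gaussian noise convolved to the stated correlation length,
    renormalized to zero mean / unit variance."""
    w = rng.standard_normal(shape)
    if smoothness > 0:
        w = ndimage.gaussian_filter(w, sigma=smoothness, mode="reflect")
    sd = w.std()
    return (w - w.mean()) / (sd if sd > 0 else 1.0)


def simulate_phantom_pair(config: PhantomConfig) -> tuple[ParametricMapSet, RoiLabelmap]:
    """Nine parametric maps plus a CET/NEL/necrosis labelmap on one grid.

    Voxel values in each ROI are ``mean + sd * smooth_noise`` with the
    smooth field renormalized to unit marginal variance, so per-ROI
    distributions match the configured means/SDs within sampling error.
    """
    rng = np.random.default_rng(config.seed)
    geom = config.roi_geometry
    shape = tuple(config.grid_shape)

    nec = _ellipsoid_mask(shape, geom.center, geom.necrosis_radii)
    cet_outer = _ellipsoid_mask(shape, geom.center, geom.cet_radii)
    nel_outer = _ellipsoid_mask(shape, geom.center, geom.nel_radii)
    cet = cet_outer & ~nec
    nel = nel_outer & ~cet_outer

    labels = np.zeros(shape, dtype=np.int16)
    labels[nel] = schema.LABEL_NEL
    labels[cet] = schema.LABEL_CET
    labels[nec] = schema.LABEL_NECROSIS

    region_masks = {
        "background": labels == schema.LABEL_BACKGROUND,
        "CET": cet,
        "NEL": nel,
        "necrosis": nec,
    }

    affine = np.diag(list(config.voxel_spacing) + [1.0])
    maps: dict[str, np.ndarray] = {}
    for m in schema.MAP_NAMES:
        noise = _smooth_unit_noise(shape, config.smoothness, rng)
        arr = np.zeros(shape)
        for region, mask in region_masks.items():
            mu = float(config.per_map_means[m][region])
            sd = float(config.per_map_sds[m][region])
            arr[mask] = mu + sd * noise[mask]
        maps[m] = arr

    return (
        ParametricMapSet(maps=maps, affine=affine),
        RoiLabelmap(labels=labels, affine=affine),
    )
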