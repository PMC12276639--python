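"""Diagnostic-performance evaluation and cohort statistics.

* rank-based AUC (ties count 1/2) with a 95% CI from the DeLong
  asymptotic paired-rank variance;
* Youden-optimal cutoff: candidates are midpoints between adjacent
  distinct scores plus +/-infinity, classification is ``score > cutoff``,
  ties in the objective resolve to the lowest qualifying cutoff;
* two-group comparisons (independent-samples t-test, chi-square without
  continuity correction so small tables are hand-checkable);
* AUC-based sample size under the Hanley-McNeil exponential variance
  model with an explicit negative:positive allocation ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PerformanceReport",
    "roc_auc",
    "youden_cutoff",
    "compare_groups",
    "auc_sample_size",
    "evaluate_models",
    "pool_longitudinal",
]


@dataclass(frozen=True)
class PerformanceReport:
    """Table-style diagnostic summary for one model on one cohort."""

    target: str
    flavor: str
    cohort: str
    n: int
    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fn: int
    tn: int
    fp: int
    cutoff_source: str = "training"

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci95_low"], d["ci95_high"] = self.ci95
        del d["ci95"]
        return d


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
    return y


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Rank-based AUC with an asymptotic DeLong confidence interval.

    The point estimate equals the fraction of concordant
    positive-negative pairs, ties counted one half.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)

    all_r = _midranks(np.concatenate([pos, neg]))
    r_pos = _midranks(pos)
    r_neg = _midranks(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)

    # DeLong structural components
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    # the CI must bracket the estimate even when variance collapses
    lo = min(lo, auc)
    hi = max(hi, auc)
    return float(auc), (float(lo), float(hi))


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden_j: float
    tp: int
    fn: int
    tn: int
    fp: int
    tie: bool


def _confusion(scores: np.ndarray, y: np.ndarray, cutoff: float):
    pred = scores > cutoff
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return tp, fn, tn, fp


def youden_cutoff(scores, labels) -> YoudenResult:
    """Cutoff maximizing sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct scores plus
    +/-inf; prediction is positive when ``score > cutoff``.  Objective
    ties resolve to the lowest qualifying cutoff (flagged).
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    distinct = np.unique(s)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    best = None
    tie = False
    for c in candidates:
        tp, fn, tn, fp = _confusion(s, y, c)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec, tp, fn, tn, fp)
            tie = False
        elif abs(j - best[0]) <= 1e-12 and c != best[1]:
            tie = True  # keep the lowest qualifying cutoff
    j, c, sens, spec, tp, fn, tn, fp = best
    return YoudenResult(
        cutoff=float(c),
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float((tp + tn) / len(y)),
        youden_j=float(j),
        tp=tp, fn=fn, tn=tn, fp=fp,
        tie=tie,
    )


def compare_groups(a=None, b=None, table=None):
    """Two-sided two-group comparison.

    Numeric samples ``a``, ``b`` -> independent-samples t-test; a count
    ``table`` (2 x k) -> chi-square without continuity correction.
    Returns ``(statistic, p_value)``.
    """
    if table is not None:
        t = np.asarray(table, dtype=float)
        if t.shape[0] != 2 or t.ndim != 2:
            raise ValueError("table must be 2 x k")
        stat, p, _, _ = stats.chi2_contingency(t, correction=False)
        return float(stat), float(p)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, g in (("a", a), ("b", b)):
        if np.var(g) == 0:
            raise ValueError(f"group {name!r} has zero variance")
    stat, p = stats.ttest_ind(a, b)
    return float(stat), float(p)


def _hanley_mcneil_var(auc: float, m: int, n: int) -> float:
    """AUC variance under the exponential (Hanley-McNeil) model.

    ``m`` positives, ``n`` negatives.
    """
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)
    ) / (m * n)


def auc_sample_size(
    auc_alt: float,
    auc_null: float = 0.5,
    alpha: float = 0.05,
    beta: float = 0.20,
    allocation_ratio: float = 1.0,
    two_sided: bool = True,
) -> int:
    """Smallest total n so the asymptotic AUC test attains power 1-beta.

    ``allocation_ratio`` is negatives per positive (e.g. 3.0 for a 25%
    positive-class prevalence).  Variances under the null and the
    alternative follow the Hanley-McNeil exponential model.
    """
    if not (0.5 <= auc_null < auc_alt < 1.0):
        raise ValueError("need 0.5 <= auc_null < auc_alt < 1")
    for name, v in (("alpha", alpha), ("beta", beta)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    if allocation_ratio <= 0:
        raise ValueError("allocation_ratio must be positive")
    z_a = stats.norm.ppf(1.0 - (alpha / 2.0 if two_sided else alpha))
    z_b = stats.norm.ppf(1.0 - beta)
    delta = auc_alt - auc_null
    for m in range(2, 100000):
        n = max(2, int(np.ceil(m * allocation_ratio)))
        se0 = np.sqrt(_hanley_mcneil_var(auc_null, m, n))
        se1 = np.sqrt(_hanley_mcneil_var(auc_alt, m, n))
        power = stats.norm.cdf((delta - z_a * se0) / se1)
        if power >= 1.0 - beta:
            return m + n
    raise RuntimeError("sample size search did not converge")


def pool_longitudinal(cohort) -> tuple:
    """Stack both timepoints of a paired cohort: N = 2 x n_patients rows.

    Each scan keeps its surgery-matched genotype label.
    """
    import pandas as pd

    if cohort.features_t2 is None:
        raise ValueError("cohort has no second timepoint to pool")
    t1 = cohort.features_t1.copy()
    t2 = cohort.features_t2.copy()
    t1.index = [f"{i}_t1" for i in t1.index]
    t2.index = [f"{i}_t2" for i in t2.index]
    X = pd.concat([t1, t2], axis=0)
    y = pd.Series(
        np.concatenate([cohort.labels.to_numpy(), cohort.labels.to_numpy()]),
        index=X.index,
        name=cohort.labels.name,
    )
    return X, y


def evaluate_models(models, cohorts: dict) -> list[PerformanceReport]:
    """One report per model x cohort.

    ``cohorts`` maps a cohort name to ``(X, y)``.  Thresholds reuse each
    model's stored training (Youden) cutoff; apparent performance on the
    training cohort therefore reproduces the stored fit.
    """
    reports = []
    for model in models:
        for name, (X, y) in cohorts.items():
            missing = [f for f in model.selected if f not in X.columns]
            if missing:
                raise ValueError(
                    f"cohort {name!r} lacks features required by the model: {missing}"
                )
            scores = model.predict_proba(X)
            yv = np.asarray(y).astype(int)
            auc, ci = roc_auc(scores, yv)
            tp, fn, tn, fp = _confusion(np.asarray(scores), yv, model.threshold)
            reports.append(
                PerformanceReport(
                    target=model.target,
                    flavor=model.flavor,
                    cohort=name,
                    n=len(yv),
                    auc=auc,
                    ci95=ci,
                    cutoff=model.threshold,
                    sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
                    specificity=tn / (tn + fp) if tn + fp else float("nan"),
                    accuracy=(tp + tn) / len(yv),
                    tp=tp, fn=fn, tn=tn, fp=fp,
                )
            )
    return reports
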