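"""Temporal-stability screening of radiomics features.

For patients whose genotype is unchanged between the initial and the
recurrence scan, each feature's agreement across the two timepoints is
quantified by the intraclass correlation coefficient; features with
ICC > 0.5 (strict) are kept as temporally stable.

The ICC variant is two-way mixed effects, absolute agreement, single
measurement — ICC(A,1): the two occasions are fixed (same scanner and
protocol at two visits), and systematic initial-vs-recurrence shifts
should count against agreement.  Computed from the two-way ANOVA mean
squares:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

with n subjects and k = 2 occasions.  Negative estimates are kept as
computed; the filter is a strict point-estimate threshold, not a test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StabilityReport", "icc", "stable_features"]


@dataclass
class StabilityReport:
    """Per-feature ICC estimates and the stable set."""

    icc_by_feature: pd.Series
    n_subjects: int
    threshold: float = 0.5
    genotype_context: str = "IDH"
    variant: str = "ICC(A,1)"
    excluded_subjects: list[str] = field(default_factory=list)

    @property
    def stable_set(self) -> list[str]:
        icc = self.icc_by_feature
        return icc.index[icc > self.threshold].tolist()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"icc": self.icc_by_feature})
        df["stable"] = df["icc"] > self.threshold
        df.index.name = "feature"
        return df


def icc(paired) -> float:
    """ICC(A,1) of an (n_subjects x 2) paired-measurement array.

    Conventions for degenerate input: all values identical -> 1.0
    (perfect agreement); zero between- and within-subject variance
    asymmetries that make the denominator vanish -> NaN.
    """
    x = np.asarray(paired, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("paired must be an (n_subjects, 2) array")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("paired measurements must be finite")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(x, grand):
        return 1.0

    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    mse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum() / (
        (n - 1) * (k - 1)
    )
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


def stable_features(
    t1: pd.DataFrame,
    t2: pd.DataFrame,
    subjects=None,
    threshold: float = 0.5,
    genotype_context: str = "IDH",
) -> StabilityReport:
    """ICC per feature over the listed unchanged-genotype subjects.

    ``subjects`` defaults to the subjects present in both tables (the
    IDH context, where genotype is unchanged in everyone); for the EGFR
    context pass only subjects with concordant amplification status at
    both surgeries.  Subjects missing a timepoint are reported in
    ``excluded_subjects``, never silently dropped.
    """
    if list(t1.columns) != list(t2.columns):
        raise ValueError("t1 and t2 must share the same feature schema")
    if subjects is None:
        subjects = [s for s in t1.index if s in t2.index]
    subjects = list(subjects)
    excluded = [s for s in subjects if s not in t1.index or s not in t2.index]
    used = [s for s in subjects if s not in excluded]
    if len(used) < 3:
        raise ValueError(
            f"need >= 3 subjects present at both timepoints, got {len(used)}"
        )
    a = t1.loc[used]
    b = t2.loc[used]
    estimates = {
        feat: icc(np.column_stack([a[feat].to_numpy(), b[feat].to_numpy()]))
        for feat in t1.columns
    }
    return StabilityReport(
        icc_by_feature=pd.Series(estimates, name="icc"),
        n_subjects=len(used),
        threshold=threshold,
        genotype_context=genotype_context,
        excluded_subjects=excluded,
    )
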