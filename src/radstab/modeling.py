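"""Best and concordant diagnostic models.

Two-stage construction, for each genotype target:

1. L1-penalized logistic regression over a lambda grid, lambda chosen by
   stratified 10-fold cross-validated binomial deviance (lambda_min by
   default, lambda_1se available); the nonzero-coefficient features are
   the selected set.
2. Unpenalized logistic refit on the selected features; the decision
   threshold is the Youden-optimal cutoff on the training probabilities.

The "best" model searches all features of the cross-sectional table; the
"concordant" model restricts the search to the temporally stable set
from the longitudinal ICC filter.  Features are z-scored with
training-set statistics before the penalty so heterogeneous units are
penalized fairly; lambda is on the mean-loss (glmnet) scale,
``C = 1 / (n * lambda)`` for scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .evaluation import youden_cutoff
from .stability import StabilityReport

__all__ = [
    "ModelSpec",
    "fit_lasso_selection",
    "build_model",
    "make_best_model",
    "make_concordant_model",
]

_SEPARATION_COEF_BOUND = 20.0  # |coef| on z-scored data beyond which we suspect separation


class DegenerateLabelsError(ValueError):
    """y contains a single class."""


@dataclass
class ModelSpec:
    """Everything needed to score new data bit-reproducibly."""

    target: str
    flavor: str
    selected: list[str]
    coefficients: dict[str, float]
    intercept: float
    center: dict[str, float]
    scale: dict[str, float]
    lambda_: float
    threshold: float
    metadata: dict = field(default_factory=dict)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected if f not in X.columns]
        if missing:
            raise ValueError(f"feature table lacks model features: {missing}")
        lp = np.full(len(X), self.intercept, dtype=float)
        for f in self.selected:
            z = (X[f].to_numpy(dtype=float) - self.center[f]) / self.scale[f]
            lp += self.coefficients[f] * z
        return lp

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X) > self.threshold).astype(int)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target": self.target,
            "flavor": self.flavor,
            "selected": self.selected,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "center": self.center,
            "scale": self.scale,
            "lambda": self.lambda_,
            "threshold": self.threshold,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            target=d["target"], flavor=d["flavor"], selected=d["selected"],
            coefficients=d["coefficients"], intercept=d["intercept"],
            center=d["center"], scale=d["scale"], lambda_=d["lambda"],
            threshold=d["threshold"], metadata=d.get("metadata", {}),
        )


def _validate_xy(X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("y must contain both classes")
    if np.bincount(y).min() < 2:
        raise DegenerateLabelsError("need at least 2 subjects per class")
    complete = ~X.isna().any(axis=1).to_numpy()
    excluded = X.index[~complete].tolist()
    return X.loc[complete], y[complete], excluded


def _zscore(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = X.to_numpy(dtype=float)
    center = arr.mean(axis=0)
    scale = arr.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns stay zero after centering
    return (arr - center) / scale, center, scale


def _l1_fit(Z: np.ndarray, y: np.ndarray, lam: float, seed: int) -> LogisticRegression:
    n = len(y)
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n * lam),
        solver="liblinear",
        max_iter=2000,
        tol=1e-6,
        random_state=seed,
    )
    clf.fit(Z, y)
    return clf


def default_lambda_grid(Z: np.ndarray, y: np.ndarray, n_lambdas: int = 25) -> np.ndarray:
    """Log-spaced grid from lambda_max (all coefficients zero) downward."""
    n = len(y)
    ybar = y.mean()
    lam_max = np.abs(Z.T @ (y - ybar)).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)


def fit_lasso_selection(
    X: pd.DataFrame,
    y,
    lambda_grid=None,
    cv_folds: int = 10,
    seed: int = 0,
    selection: str = "min",
    lambda_override: float | None = None,
) -> tuple[list[str], float, pd.DataFrame]:
    """L1 feature selection with CV-chosen penalty.

    Returns ``(selected_names, lambda, cv_table)``.  ``selection`` is
    ``"min"`` (minimum mean CV deviance) or ``"1se"`` (sparsest lambda
    within one standard error of the minimum).  ``lambda_override``
    skips CV and fits at the given penalty.  Rows with missing values
    are excluded (they are reported by the pipeline, never imputed), and
    exactly duplicated columns are collapsed to their first occurrence
    before fitting, so at most one of an identical pair is selected.
    """
    X, y, _excluded = _validate_xy(X, y)
    # for exactly duplicated columns the L1 optimum is non-unique and the
    # solver splits weight arbitrarily; keep the first of each duplicate
    # group so selection returns one representative, deterministically
    dup = X.T.duplicated()
    if dup.any():
        X = X.loc[:, ~dup.to_numpy()]
    Z, center, scale = _zscore(X)

    if lambda_override is not None:
        clf = _l1_fit(Z, y, lambda_override, seed)
        sel = [X.columns[i] for i in np.flatnonzero(clf.coef_[0])]
        return sel, float(lambda_override), pd.DataFrame()

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(Z, y)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    folds = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    deviance = np.zeros((cv_folds, len(lambda_grid)))
    for k, (tr, te) in enumerate(folds.split(Z, y)):
        for j, lam in enumerate(lambda_grid):
            clf = _l1_fit(Z[tr], y[tr], lam, seed)
            p = clf.predict_proba(Z[te])[:, 1]
            deviance[k, j] = 2.0 * log_loss(y[te], p, labels=[0, 1])

    mean_dev = deviance.mean(axis=0)
    se_dev = deviance.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    j_min = int(np.argmin(mean_dev))
    if selection == "min":
        j_star = j_min
    elif selection == "1se":
        bound = mean_dev[j_min] + se_dev[j_min]
        # grid is sorted descending, so the first qualifying index is sparsest
        j_star = int(np.flatnonzero(mean_dev <= bound)[0])
    else:
        raise ValueError("selection must be 'min' or '1se'")
    lam = float(lambda_grid[j_star])

    clf = _l1_fit(Z, y, lam, seed)
    sel = [X.columns[i] for i in np.flatnonzero(clf.coef_[0])]
    cv_table = pd.DataFrame(
        {"lambda": lambda_grid, "mean_deviance": mean_dev, "se_deviance": se_dev}
    )
    return sel, lam, cv_table


def build_model(
    selected: list[str],
    X: pd.DataFrame,
    y,
    flavor: str,
    target: str,
    lambda_: float = float("nan"),
    seed: int = 0,
) -> ModelSpec:
    """Unpenalized logistic refit on the selected features.

    Perfect separation (runaway coefficients) falls back to a
    ridge-stabilized fit, flagged in the metadata.  An empty selection
    yields an intercept-only model (constant score), also flagged.
    """
    X, y, excluded = _validate_xy(X, y)
    meta: dict = {"seed": seed, "excluded_rows": excluded, "separation_fallback": False}

    if not selected:
        p1 = float(y.mean())
        intercept = float(np.log(p1 / (1.0 - p1)))
        meta["intercept_only"] = True
        return ModelSpec(
            target=target, flavor=flavor, selected=[], coefficients={},
            intercept=intercept, center={}, scale={}, lambda_=lambda_,
            threshold=0.5, metadata=meta,
        )

    Xs = X[selected]
    Z, center, scale = _zscore(Xs)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    clf.fit(Z, y)
    fitted = clf.predict_proba(Z)[:, 1]
    separated = bool(np.all(np.abs(fitted - y) < 1e-3))
    if separated or np.abs(clf.coef_).max() > _SEPARATION_COEF_BOUND:
        clf = LogisticRegression(l1_ratio=0.0, C=1.0, solver="lbfgs", max_iter=5000)
        clf.fit(Z, y)
        meta["separation_fallback"] = True

    spec = ModelSpec(
        target=target,
        flavor=flavor,
        selected=list(selected),
        coefficients={f: float(c) for f, c in zip(selected, clf.coef_[0])},
        intercept=float(clf.intercept_[0]),
        center={f: float(c) for f, c in zip(selected, center)},
        scale={f: float(s) for f, s in zip(selected, scale)},
        lambda_=float(lambda_),
        threshold=0.5,
        metadata=meta,
    )
    probs = spec.predict_proba(X)
    if np.unique(probs).size > 1:
        yr = youden_cutoff(probs, y)
        spec.threshold = yr.cutoff
        meta["training_youden_j"] = yr.youden_j
    meta["training_fitted_probabilities_checksum"] = float(np.sum(probs))
    return spec


def make_best_model(
    X: pd.DataFrame,
    y,
    target: str,
    cv_folds: int = 10,
    seed: int = 0,
    selection: str = "min",
) -> ModelSpec:
    """LASSO over all features of the cross-sectional table, then refit."""
    sel, lam, _ = fit_lasso_selection(
        X, y, cv_folds=cv_folds, seed=seed, selection=selection
    )
    return build_model(sel, X, y, flavor="best", target=target, lambda_=lam, seed=seed)


def make_concordant_model(
    X: pd.DataFrame,
    y,
    stability: StabilityReport,
    target: str,
    cv_folds: int = 10,
    seed: int = 0,
    selection: str = "min",
) -> ModelSpec:
    """LASSO restricted to the temporally stable features, then refit.

    Trained on the cross-sectional table (both flavors are evaluated on
    the same cohorts); selection is constrained to
    ``stability.stable_set`` of the matching genotype context.
    """
    if stability.genotype_context != target:
        raise ValueError(
            f"stability report context {stability.genotype_context!r} "
            f"does not match target {target!r}"
        )
    stable = [f for f in stability.stable_set if f in X.columns]
    if not stable:
        raise ValueError(
            "stable feature set is empty (or disjoint from the feature table); "
            "a concordant model cannot be built"
        )
    sel, lam, _ = fit_lasso_selection(
        X[stable], y, cv_folds=cv_folds, seed=seed, selection=selection
    )
    model = build_model(
        sel, X, y, flavor="concordant", target=target, lambda_=lam, seed=seed
    )
    assert set(model.selected) <= set(stable)
    return model
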