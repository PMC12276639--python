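"""LASSO selection, logistic refit, and the best/concordant constructions."""

import numpy as np
import pandas as pd
import pytest

from radstab.evaluation import roc_auc
from radstab.modeling import (
    DegenerateLabelsError,
    ModelSpec,
    build_model,
    fit_lasso_selection,
    make_best_model,
    make_concordant_model,
)
from radstab.stability import StabilityReport
from radstab.synthetic import CohortConfig, simulate_feature_cohort


def _cohort(seed=0, **kw):
    defaults = dict(n_patients=150, prevalence=0.5, n_features=60,
                    n_informative=4, effect_size=1.2)
    defaults.update(kw)
    return simulate_feature_cohort(CohortConfig(seed=seed, **defaults))


class TestLassoSelection:
    def test_lambda_above_max_shrinks_everything(self):
        c = _cohort()
        sel, lam, _ = fit_lasso_selection(c.features_t1, c.labels, lambda_override=5.0)
        assert sel == []

    def test_duplicated_column_selected_at_most_once(self):
        c = _cohort(seed=1)
        X = c.features_t1.copy()
        f = c.informative_features[0]
        X["dup_col"] = X[f].to_numpy()
        for lam in (0.1, 0.02, 0.005):
            sel, _, _ = fit_lasso_selection(X, c.labels, lambda_override=lam)
            assert not (f in sel and "dup_col" in sel)
        sel, _, _ = fit_lasso_selection(X, c.labels, seed=0)
        assert not (f in sel and "dup_col" in sel)

    def test_informative_recovery_with_sparse_rule(self):
        """d = 1.2, n = 300, p = 200: near-full recovery, few false hits."""
        rec, fps = [], []
        for seed in range(5):
            c = _cohort(seed=seed, n_patients=300, n_features=200, n_informative=5)
            sel, _, _ = fit_lasso_selection(c.features_t1, c.labels, seed=seed,
                                            selection="1se")
            info = set(c.informative_features)
            rec.append(len(info & set(sel)))
            fps.append(len(set(sel) - info))
        assert np.mean(rec) >= 4.0
        assert np.mean(fps) <= 10.0

    def test_null_features_rarely_selected_at_1se(self):
        empty = 0
        for seed in range(5):
            c = _cohort(seed=seed, n_patients=200, n_features=100,
                        n_informative=0, effect_size=0.0)
            sel, _, _ = fit_lasso_selection(c.features_t1, c.labels, seed=seed,
                                            selection="1se")
            empty += len(sel) == 0
        assert empty >= 4  # >= 80% of seeds

    def test_deterministic_given_seed(self):
        c = _cohort(seed=3)
        a = fit_lasso_selection(c.features_t1, c.labels, seed=5)
        b = fit_lasso_selection(c.features_t1, c.labels, seed=5)
        assert a[0] == b[0] and a[1] == b[1]

    def test_single_class_labels_rejected(self):
        c = _cohort()
        with pytest.raises(DegenerateLabelsError):
            fit_lasso_selection(c.features_t1, np.ones(len(c.labels), int))


class TestBuildModel:
    def test_positive_direction_for_positively_associated_feature(self, rng):
        x = rng.normal(size=200)
        y = (x + rng.normal(scale=0.5, size=200) > 0).astype(int)
        X = pd.DataFrame({"f": x})
        m = build_model(["f"], X, y, flavor="best", target="IDH")
        assert m.coefficients["f"] > 0

    def test_scoring_round_trip_reproduces_training_probabilities(self):
        c = _cohort(seed=4)
        sel, lam, _ = fit_lasso_selection(c.features_t1, c.labels, seed=4)
        m = build_model(sel, c.features_t1, c.labels, "best", "IDH", lambda_=lam)
        probs = m.predict_proba(c.features_t1)
        assert np.sum(probs) == pytest.approx(
            m.metadata["training_fitted_probabilities_checksum"], abs=1e-9
        )

    def test_json_round_trip_bit_identical_scores(self, tmp_path):
        c = _cohort(seed=5)
        m = build_model(c.informative_features, c.features_t1, c.labels, "best", "IDH")
        p = tmp_path / "model.json"
        m.to_json(p)
        m2 = ModelSpec.from_json(p)
        assert np.array_equal(m.predict_proba(c.features_t1),
                              m2.predict_proba(c.features_t1))

    def test_permuted_labels_give_chance_training_auc(self, rng):
        c = _cohort(seed=6, n_patients=300)
        y_perm = c.labels.sample(frac=1.0, random_state=1).to_numpy()
        m = build_model(c.informative_features[:2], c.features_t1, y_perm,
                        "best", "IDH")
        auc, _ = roc_auc(m.predict_proba(c.features_t1), y_perm)
        assert auc == pytest.approx(0.5, abs=0.08)

    def test_perfect_separation_falls_back_to_ridge(self, rng):
        x = np.concatenate([rng.normal(-5, 0.1, 30), rng.normal(5, 0.1, 30)])
        y = (x > 0).astype(int)
        X = pd.DataFrame({"f": x})
        m = build_model(["f"], X, y, "best", "IDH")
        assert m.metadata["separation_fallback"]
        assert np.isfinite(m.coefficients["f"])

    def test_empty_selection_yields_flagged_intercept_model(self):
        c = _cohort(seed=7)
        m = build_model([], c.features_t1, c.labels, "best", "IDH")
        assert m.metadata["intercept_only"]
        assert np.unique(m.predict_proba(c.features_t1)).size == 1


class TestModelFlavors:
    def _stability_report(self, features, stable):
        icc = pd.Series({f: (0.9 if f in stable else 0.1) for f in features})
        return StabilityReport(icc_by_feature=icc, n_subjects=38,
                               genotype_context="IDH")

    def test_concordant_selection_is_subset_of_stable_set(self):
        c = _cohort(seed=8)
        stable = list(c.features_t1.columns[:30])
        rep = self._stability_report(c.features_t1.columns, stable)
        m = make_concordant_model(c.features_t1, c.labels, rep, "IDH", seed=8)
        assert set(m.selected) <= set(stable)
        assert m.flavor == "concordant"

    def test_all_stable_concordant_coincides_with_best(self):
        c = _cohort(seed=9)
        rep = self._stability_report(c.features_t1.columns, list(c.features_t1.columns))
        best = make_best_model(c.features_t1, c.labels, "IDH", seed=9)
        conc = make_concordant_model(c.features_t1, c.labels, rep, "IDH", seed=9)
        assert best.selected == conc.selected
        assert best.coefficients == conc.coefficients

    def test_excluding_informative_features_costs_training_auc(self):
        c = _cohort(seed=10, n_patients=250, effect_size=1.5)
        stable = [f for f in c.features_t1.columns
                  if f not in set(c.informative_features)]
        rep = self._stability_report(c.features_t1.columns, stable)
        best = make_best_model(c.features_t1, c.labels, "IDH", seed=10)
        conc = make_concordant_model(c.features_t1, c.labels, rep, "IDH", seed=10)
        auc_best, _ = roc_auc(best.predict_proba(c.features_t1), c.labels)
        auc_conc, _ = roc_auc(conc.predict_proba(c.features_t1), c.labels)
        assert auc_conc <= auc_best

    def test_empty_stable_set_is_informative_error(self):
        c = _cohort(seed=11)
        rep = self._stability_report(c.features_t1.columns, [])
        with pytest.raises(ValueError, match="empty"):
            make_concordant_model(c.features_t1, c.labels, rep, "IDH")

    def test_context_mismatch_rejected(self):
        c = _cohort(seed=12)
        rep = self._stability_report(c.features_t1.columns,
                                     list(c.features_t1.columns))
        with pytest.raises(ValueError, match="context"):
            make_concordant_model(c.features_t1, c.labels, rep,
                                  "EGFR-in-IDH-wildtype")

    def test_strong_signal_training_auc_high(self):
        c = _cohort(seed=13, n_patients=300, n_informative=8, effect_size=1.5)
        best = make_best_model(c.features_t1, c.labels, "IDH", seed=13)
        auc, _ = roc_auc(best.predict_proba(c.features_t1), c.labels)
        assert auc > 0.9
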