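"""Designed properties of the synthetic cohorts and phantoms."""

import numpy as np
import pytest
from scipy.stats import norm

from radstab import schema
from radstab.evaluation import roc_auc
from radstab.heterogeneity import compare_rois
from radstab.synthetic import (
    CohortConfig,
    ConfigurationError,
    EllipsoidShells,
    GeometryError,
    PhantomConfig,
    simulate_feature_cohort,
    simulate_phantom_pair,
    simulate_study,
)


class TestCohortConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"prevalence": 0.0}, "prevalence"),
            ({"prevalence": 1.5}, "prevalence"),
            ({"n_informative": 300, "n_features": 200}, "n_informative"),
            ({"feature_correlation": 1.0}, "feature_correlation"),
            ({"stability_rho": 1.2}, "stability_rho"),
            ({"unstable_fraction": -0.1}, "unstable_fraction"),
        ],
    )
    def test_invalid_fields_named_in_error(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            CohortConfig(**kwargs)


class TestFeatureCohort:
    def test_seed_determinism_bit_identical(self):
        cfg = CohortConfig(n_patients=50, n_features=30, paired=True, seed=5)
        a = simulate_feature_cohort(cfg)
        b = simulate_feature_cohort(cfg)
        assert a.features_t1.equals(b.features_t1)
        assert a.features_t2.equals(b.features_t2)
        assert a.labels.equals(b.labels)

    def test_fixed_count_label_allocation(self):
        cfg = CohortConfig(n_patients=312, prevalence=0.25, n_features=10, seed=1)
        c = simulate_feature_cohort(cfg)
        assert c.labels.sum() == round(312 * 0.25)

    def test_null_effect_features_discriminate_at_chance(self):
        """d = 0: every feature's AUC is within 3 SE of 0.5 at n = 400."""
        cfg = CohortConfig(
            n_patients=400, prevalence=0.5, n_features=20, n_informative=5,
            effect_size=0.0, seed=9,
        )
        c = simulate_feature_cohort(cfg)
        m = n = 200
        se = np.sqrt((m + n + 1) / (12 * m * n))  # null AUC standard error
        for f in c.features_t1.columns:
            auc, _ = roc_auc(c.features_t1[f], c.labels)
            assert abs(auc - 0.5) < 3 * se

    def test_single_feature_auc_matches_normal_shift_closed_form(self):
        """AUC of a d-shifted unit-variance feature is Phi(d / sqrt 2).

        The closed form was verified by brute-force pair counting over
        the generated sample (roc_auc is rank-based, i.e. exactly the
        pair-counting estimator).
        """
        cfg = CohortConfig(
            n_patients=2000, prevalence=0.5, n_features=5, n_informative=1,
            effect_size=1.5, seed=7,
        )
        c = simulate_feature_cohort(cfg)
        f = c.informative_features[0]
        auc, _ = roc_auc(c.features_t1[f], c.labels)
        assert auc == pytest.approx(norm.cdf(1.5 / np.sqrt(2)), abs=0.02)

    def test_between_timepoint_correlation_tracks_assigned_rho(self):
        for rho in (0.0, 0.5, 0.95):
            cfg = CohortConfig(
                n_patients=1000, prevalence=0.25, n_features=15, n_informative=4,
                effect_size=1.0, stability_rho=rho, paired=True, seed=11,
            )
            c = simulate_feature_cohort(cfg)
            for f in c.features_t1.columns:
                r = np.corrcoef(c.features_t1[f], c.features_t2[f])[0, 1]
                assert abs(r - rho) < 0.1

    def test_unstable_fraction_assigns_low_rho_to_informative_subset(self):
        cfg = CohortConfig(
            n_patients=100, n_features=40, n_informative=10, effect_size=1.0,
            stability_rho=0.9, unstable_fraction=0.5, unstable_rho=0.1,
            paired=True, seed=2,
        )
        c = simulate_feature_cohort(cfg)
        info = c.truth[c.truth["informative"]]
        assert (info["stability_rho"] == 0.1).sum() == 5
        assert (info["stability_rho"] == 0.9).sum() == 5

    def test_tables_share_ids_and_schema(self):
        cfg = CohortConfig(n_patients=40, n_features=25, paired=True, seed=3)
        c = simulate_feature_cohort(cfg)
        assert list(c.features_t1.index) == list(c.features_t2.index)
        assert list(c.features_t1.columns) == list(c.features_t2.columns)
        assert list(c.features_t1.index) == list(c.labels.index)


class TestStudyScenarios:
    def test_scenario_names_validated(self):
        with pytest.raises(ConfigurationError):
            simulate_study("nonsense", seed=0)

    def test_cohort_sizes_and_shared_schema(self):
        cross, lon = simulate_study("stable_signal", seed=0, n_cross=80, n_long=20,
                                    n_features=50)
        assert len(cross.features_t1) == 80
        assert len(lon.features_t1) == len(lon.features_t2) == 20
        assert list(cross.features_t1.columns) == list(lon.features_t1.columns)

    def test_stable_scenario_truth_structure(self):
        cross, lon = simulate_study("stable_signal", seed=1, n_features=60)
        truth = cross.truth
        info = truth[truth["informative"]]
        assert len(info) == 20
        assert (info["stability_rho"] <= 0.2).sum() == 10
        assert (info["stability_rho"] >= 0.9).sum() == 10


class TestPhantom:
    def test_nine_maps_on_one_grid(self, small_phantom_pair):
        map_set, rois = small_phantom_pair
        assert len(map_set.maps) == 9
        assert set(map_set.maps) == set(schema.MAP_NAMES)
        assert all(m.shape == rois.labels.shape for m in map_set.maps.values())

    def test_rois_pairwise_disjoint(self, small_phantom_pair):
        _, rois = small_phantom_pair
        # integer labels are exclusive by construction; all three present
        present = set(np.unique(rois.labels))
        assert {1, 2, 3} <= present

    def test_seed_determinism(self):
        cfg = PhantomConfig(grid_shape=(16, 16, 16), seed=4)
        a, _ = simulate_phantom_pair(cfg)
        b, _ = simulate_phantom_pair(cfg)
        for m in schema.MAP_NAMES:
            assert np.array_equal(a.maps[m], b.maps[m])

    def test_roi_distributions_match_design(self, phantom_pair):
        map_set, rois = phantom_pair
        cfg = PhantomConfig(seed=42)
        for m in ("ADC", "nCBV"):
            for roi in ("CET", "NEL"):
                vals = map_set.maps[m][rois.mask(roi)]
                mu = cfg.per_map_means[m][roi]
                sd = cfg.per_map_sds[m][roi]
                # the smoothed field is spatially correlated, so the ROI
                # mean wanders more than an iid bound would allow
                assert abs(vals.mean() - mu) < 0.2 * sd
                assert vals.std() == pytest.approx(sd, rel=0.2)

    def test_equal_means_give_high_intersection(self):
        means = PhantomConfig().per_map_means
        means = {m: dict(v) for m, v in means.items()}
        means["ADC"]["NEL"] = means["ADC"]["CET"]
        sds = {m: dict(v) for m, v in PhantomConfig().per_map_sds.items()}
        sds["ADC"]["NEL"] = sds["ADC"]["CET"]
        cfg = PhantomConfig(per_map_means=means, per_map_sds=sds, seed=8)
        map_set, rois = simulate_phantom_pair(cfg)
        cet = map_set.maps["ADC"][rois.mask("CET")]
        nel = map_set.maps["ADC"][rois.mask("NEL")]
        assert min(len(cet), len(nel)) >= 5000
        r = compare_rois(cet, nel)
        assert r.intersection >= 0.9

    def test_five_sd_separation_gives_near_disjoint_histograms(self):
        means = {m: dict(v) for m, v in PhantomConfig().per_map_means.items()}
        sds = {m: dict(v) for m, v in PhantomConfig().per_map_sds.items()}
        sds["ADC"]["CET"] = sds["ADC"]["NEL"] = 0.1
        means["ADC"]["CET"] = means["ADC"]["NEL"] + 5 * 0.1
        cfg = PhantomConfig(per_map_means=means, per_map_sds=sds, seed=8)
        map_set, rois = simulate_phantom_pair(cfg)
        r = compare_rois(
            map_set.maps["ADC"][rois.mask("CET")],
            map_set.maps["ADC"][rois.mask("NEL")],
        )
        assert r.intersection <= 0.05

    def test_overlapping_geometry_rejected(self):
        with pytest.raises(GeometryError, match="nested"):
            EllipsoidShells(
                necrosis_radii=(5, 5, 5), cet_radii=(4, 4, 4), nel_radii=(10, 10, 10)
            )
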