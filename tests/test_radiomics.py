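"""First-order, shape and texture features, and full-vector assembly."""

import numpy as np
import pytest

from radstab import schema
from radstab.extract import extract_all
from radstab.firstorder import first_order_features
from radstab.image_io import ParametricMapSet, RoiLabelmap
from radstab.shape import shape_features
from radstab.texture import (
    DiscretizationPolicy,
    _glcm_features,
    _glcm_matrix,
    discretize,
    texture_features,
)


class TestFirstOrder:
    def test_constant_roi_degenerate_conventions(self):
        fo = first_order_features(np.full(50, 7.0))
        assert fo["Mean"] == 7.0
        assert fo["Variance"] == 0.0
        assert fo["Entropy"] == 0.0
        assert fo["Uniformity"] == 1.0
        assert fo["Skewness"] == 0.0
        assert fo["Kurtosis"] == 0.0

    def test_hand_arithmetic_four_values(self):
        fo = first_order_features([1, 2, 3, 4])
        assert fo["Mean"] == pytest.approx(2.5)
        assert fo["Range"] == pytest.approx(3.0)
        assert fo["Variance"] == pytest.approx(1.25)  # population convention
        assert fo["Energy"] == pytest.approx(1 + 4 + 9 + 16)
        assert fo["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))
        assert fo["Median"] == pytest.approx(2.5)

    def test_eighteen_features_in_schema_order(self, rng):
        fo = first_order_features(rng.normal(size=100))
        assert tuple(fo) == schema.FIRST_ORDER_NAMES
        assert len(fo) == 18

    def test_moments_match_scipy(self, rng):
        """Cross-check skewness/kurtosis against scipy's estimators."""
        from scipy import stats

        v = rng.gamma(2.0, 1.0, 500)
        fo = first_order_features(v)
        assert fo["Skewness"] == pytest.approx(stats.skew(v, bias=True), rel=1e-9)
        assert fo["Kurtosis"] == pytest.approx(
            stats.kurtosis(v, bias=True, fisher=False), rel=1e-9
        )

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            first_order_features([])


@pytest.fixture(scope="module")
def digital_ball():
    zz, yy, xx = np.mgrid[:25, :25, :25]
    return ((zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= 100


class TestShape:
    def test_fourteen_features(self, digital_ball):
        sf, meta = shape_features(digital_ball)
        assert tuple(sf) == schema.SHAPE_NAMES
        assert not meta["degenerate"]

    def test_ball_against_analytic_sphere(self, digital_ball):
        """Radius-10 digital ball: mesh volume and sphericity vs. closed form."""
        sf, _ = shape_features(digital_ball, spacing=(1.0, 1.0, 1.0))
        analytic_volume = 4.0 / 3.0 * np.pi * 10.0**3
        assert sf["MeshVolume"] == pytest.approx(analytic_volume, rel=0.05)
        assert 0.97 <= sf["Sphericity"] <= 1.0

    def test_ball_symmetry(self, digital_ball):
        sf, _ = shape_features(digital_ball)
        assert 0.95 <= sf["Elongation"] <= 1.0
        assert 0.95 <= sf["Flatness"] <= 1.0

    def test_anisotropic_spacing_scales_volume(self, digital_ball):
        sf1, _ = shape_features(digital_ball, spacing=(1, 1, 1))
        sf2, _ = shape_features(digital_ball, spacing=(2, 1, 1))
        assert sf2["VoxelVolume"] == pytest.approx(2 * sf1["VoxelVolume"])

    def test_single_voxel_fallback_flagged(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        sf, meta = shape_features(m)
        assert meta["degenerate"]
        assert sf["VoxelVolume"] == 1.0
        assert len(sf) == 14


class TestTexture:
    def test_constant_roi_limits(self):
        vol = np.full((4, 4, 3), 2.5)
        tx = texture_features(vol, np.ones(vol.shape, bool))
        assert tx["glcm_JointEnergy"] == pytest.approx(1.0)
        assert tx["glcm_Contrast"] == pytest.approx(0.0)
        assert tx["glcm_Correlation"] == pytest.approx(1.0)
        assert np.all(np.isfinite(list(tx.values())))

    def test_hand_built_glcm_two_level_plane(self):
        """2x2x1 ROI, rows at levels 1 and 2, single in-plane direction.

        Along the row direction co-occurrences are (1,1) and (2,2); the
        symmetric matrix is diag(2, 2).  Across rows all pairs mix
        levels, so the symmetric matrix is anti-diagonal and the
        contrast is exactly 1.
        """
        lv = np.array([[[1], [1]], [[2], [2]]])
        along = _glcm_matrix(lv, 2, (0, 1, 0))
        assert along.tolist() == [[2.0, 0.0], [0.0, 2.0]]
        across = _glcm_matrix(lv, 2, (1, 0, 0))
        assert across.tolist() == [[0.0, 2.0], [2.0, 0.0]]
        f = _glcm_features(across)
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["JointEnergy"] == pytest.approx(0.5)

    def test_family_counts(self, rng):
        tx = texture_features(rng.random((6, 6, 6)), np.ones((6, 6, 6), bool))
        counts = {}
        for k in tx:
            fam = k.split("_")[0]
            counts[fam] = counts.get(fam, 0) + 1
        assert counts == {"glcm": 24, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}

    def test_glcm_matches_skimage_on_2d_slab(self, rng):
        """Independent cross-check of GLCM construction vs. scikit-image."""
        from skimage.feature import graycomatrix

        img = rng.integers(1, 5, size=(12, 12)).astype(np.int32)
        lv = img[:, :, None]  # one-voxel-thick 3D volume
        ours = _glcm_matrix(lv, 4, (0, 1, 0))  # along rows of the 2D image
        ref = graycomatrix(img - 1, [1], [0], levels=4, symmetric=True)[:, :, 0, 0]
        assert np.array_equal(ours, ref.astype(float))

    def test_translation_invariance_of_discretized_features(self, rng):
        vol = rng.random((7, 7, 7))
        mask = np.ones(vol.shape, bool)
        a = texture_features(vol, mask)
        b = texture_features(vol + 123.4, mask)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9, abs=1e-12), k

    def test_rotation_invariance_of_direction_aggregates(self, rng):
        vol = rng.random((8, 8, 8))
        mask = np.ones(vol.shape, bool)
        a = texture_features(vol, mask)
        b = texture_features(np.rot90(vol, axes=(0, 1)).copy(), mask)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9, abs=1e-12), k

    def test_discretize_levels_within_bins(self, rng):
        vol = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.4
        lv = discretize(vol, mask, DiscretizationPolicy(n_bins=8))
        assert lv[~mask].max() == 0
        assert 1 <= lv[mask].min() and lv[mask].max() <= 8

    def test_tiny_roi_rejected(self):
        vol = np.ones((3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="at least 2"):
            texture_features(vol, mask)


class TestExtractAll:
    def test_full_vector_on_phantom(self, phantom_pair):
        map_set, rois = phantom_pair
        vec, rep = extract_all(map_set, rois)
        assert len(vec) == 1720
        assert vec.index.is_unique
        assert list(vec.index) == schema.all_feature_names()
        assert rep.n_missing == 0

    def test_schema_is_seed_independent(self, small_phantom_pair):
        from radstab.synthetic import PhantomConfig, simulate_phantom_pair

        map_set, rois = small_phantom_pair
        vec1, _ = extract_all(map_set, rois)
        ms2, r2 = simulate_phantom_pair(PhantomConfig(grid_shape=(24, 24, 24), seed=99))
        vec2, _ = extract_all(ms2, r2)
        assert list(vec1.index) == list(vec2.index)
        assert not np.allclose(vec1.to_numpy(), vec2.to_numpy())

    def test_empty_nel_yields_structured_missingness(self, small_phantom_pair):
        map_set, rois = small_phantom_pair
        labels = rois.labels.copy()
        labels[labels == schema.LABEL_NEL] = 0
        rois2 = RoiLabelmap(labels=labels, affine=rois.affine)
        vec, rep = extract_all(map_set, rois2)
        assert len(vec) == 1720
        # NEL block (93 x 9 + 14) and all 18 heterogeneity features missing
        expected_missing = 93 * 9 + 14 + 18
        assert rep.n_missing == expected_missing
        assert vec.notna().sum() == 1720 - expected_missing
        assert "NEL" in rep.empty_rois
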