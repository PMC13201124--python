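"""Local descriptor extraction and normalization."""

import numpy as np
import pytest

from _oracles import random_label_map
from ith3d.features import (
    FeatureConfigError,
    extract_local_features,
    normalize_features,
    window_features,
)


def feature(names, values, name):
    return values[0][names.index(name)]


class TestWindowFeatures:
    def test_first_order_closed_forms(self):
        vals, names = window_features(np.array([[1.0, 2.0, 3.0, 4.0]]),
                                      window_shape=(2, 2))
        d = dict(zip(names, vals[0]))
        assert d["firstorder_mean"] == pytest.approx(2.5)
        assert d["firstorder_energy"] == pytest.approx(30.0)
        assert d["firstorder_minimum"] == 1.0
        assert d["firstorder_range"] == 3.0
        assert d["firstorder_variance"] == pytest.approx(1.25)

    def test_constant_window_degenerate_values(self):
        vals, names = window_features(np.full((1, 8), 42.0),
                                      window_shape=(2, 2, 2))
        d = dict(zip(names, vals[0]))
        for key in ("firstorder_variance", "firstorder_entropy",
                    "glcm_contrast", "glcm_correlation", "glcm_joint_entropy",
                    "glrlm_glv", "ngtdm_contrast", "ngtdm_busyness"):
            assert d[key] == 0.0, key

    def test_checkerboard_contrast_exceeds_constant(self):
        flat = np.full((1, 4), 0.0)
        checker = np.array([[0.0, 100.0, 100.0, 0.0]])
        v_flat, names = window_features(flat, window_shape=(2, 2))
        v_chk, _ = window_features(checker, window_shape=(2, 2))
        i = names.index("glcm_contrast")
        assert v_chk[0][i] > v_flat[0][i]

    def test_matches_brute_force_reference(self, brute_reference):
        rng = np.random.default_rng(4)
        for _ in range(40):
            shape = (2, 2) if rng.random() < 0.5 else (2, 2, 2)
            n = int(np.prod(shape))
            W = rng.normal(0, rng.choice([3.0, 40.0, 150.0]), n) + rng.uniform(-300, 300)
            vals, names = window_features(W[None, :], window_shape=shape)
            ref = brute_reference(W, 25.0, shape)
            for name, v in zip(names, vals[0]):
                assert v == pytest.approx(ref[name], rel=1e-9, abs=1e-9), name

    def test_intensity_shift_leaves_texture_unchanged(self):
        rng = np.random.default_rng(5)
        W = rng.normal(0, 60, (20, 8))
        v0, names = window_features(W, window_shape=(2, 2, 2))
        v1, _ = window_features(W + 137.0, window_shape=(2, 2, 2))
        texture = [i for i, n in enumerate(names)
                   if not n.startswith("firstorder")]
        assert np.allclose(v0[:, texture], v1[:, texture])

    def test_unknown_class_rejected(self):
        with pytest.raises(FeatureConfigError):
            window_features(np.zeros((1, 8)), window_shape=(2, 2, 2),
                            classes=("firstorder", "wavelet"))


class TestExtraction:
    def test_row_count_equals_mask_size(self):
        rng = np.random.default_rng(6)
        img = rng.normal(0, 50, (6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.4
        mask[0, 0, 0] = True
        fmap = extract_local_features(img, mask)
        assert fmap.n_voxels == mask.sum()
        assert not np.isnan(fmap.values).any()

    def test_translation_equivariance(self):
        rng = np.random.default_rng(7)
        img = rng.normal(0, 50, (8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        mask[1:4, 1:4, 1:4] = True
        a = extract_local_features(img, mask)
        img_shift = np.roll(img, (2, 1, 1), axis=(0, 1, 2))
        mask_shift = np.roll(mask, (2, 1, 1), axis=(0, 1, 2))
        b = extract_local_features(img_shift, mask_shift)
        assert np.allclose(a.values, b.values)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_local_features(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))

    def test_2d_path_uses_2d_window(self):
        rng = np.random.default_rng(8)
        img = rng.normal(0, 30, (7, 7))
        mask = np.ones((7, 7), bool)
        fmap = extract_local_features(img, mask)
        assert fmap.dimensionality == "2d"
        assert fmap.n_voxels == 49


class TestNormalization:
    def test_zscore_closed_form(self):
        from ith3d.features import LocalFeatureMap

        fmap = LocalFeatureMap(
            coords=np.array([[0, 0], [0, 1], [1, 0]]),
            values=np.array([[1.0], [2.0], [3.0]]),
            feature_names=["f"], grid_shape=(2, 2), dimensionality="2d")
        out = normalize_features(fmap)
        assert out.values[:, 0] == pytest.approx([-1.224744871, 0, 1.224744871])

    def test_constant_column_dropped_and_recorded(self):
        from ith3d.features import LocalFeatureMap

        fmap = LocalFeatureMap(
            coords=np.zeros((3, 2), int),
            values=np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]),
            feature_names=["varies", "constant"], grid_shape=(3, 3),
            dimensionality="2d")
        out = normalize_features(fmap)
        assert out.feature_names == ["varies"]
        assert out.normalization["dropped_constant"] == ["constant"]

    def test_all_constant_rejected(self):
        from ith3d.features import LocalFeatureMap

        fmap = LocalFeatureMap(
            coords=np.zeros((3, 2), int), values=np.full((3, 2), 1.0),
            feature_names=["a", "b"], grid_shape=(3, 3), dimensionality="2d")
        with pytest.raises(ValueError):
            normalize_features(fmap)

    def test_columns_standardized_after_normalization(self):
        rng = np.random.default_rng(9)
        img = rng.normal(0, 80, (8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        out = normalize_features(extract_local_features(img, mask))
        assert np.abs(out.values.mean(axis=0)).max() < 1e-8
        assert np.allclose(out.values.std(axis=0), 1.0, atol=1e-8)


@pytest.fixture(scope="module")
def brute_reference():
    from _brute_features import brute_window_features

    return brute_window_features
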