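"""Attribution (exact and sampled Shapley) and the stepwise ablation."""

import numpy as np
import pytest

from _oracles import exact_shapley
from ith3d.explain import (
    AblationTrace,
    attribute_base_models,
    attribute_features,
    sampled_shapley,
    shap_ablation,
    stopping_step,
)


class TestBaseModelAttribution:
    def test_linear_attribution_matches_exhaustive_enumeration(self, trained_stack, dev_ext):
        dev, ext = dev_ext
        report = attribute_base_models(trained_stack, ext, background=ext)
        M = trained_stack.meta_features(ext)
        coef = trained_stack.meta.coef_[0]
        mean = M.mean(axis=0)

        def value(v):
            return float(coef @ v)  # linear predictor scale

        for i in range(5):
            phi = exact_shapley(value, M[i].copy(), mean.copy())
            assert np.allclose(report.matrix[i], phi, atol=1e-10)

    def test_percent_shares_sum_to_100(self, trained_stack, dev_ext):
        _, ext = dev_ext
        report = attribute_base_models(trained_stack, ext)
        assert report.percent.sum() == pytest.approx(100.0, abs=0.1)
        assert report.ranking[0] == report.entities[int(np.argmax(report.mean_abs))]

    def test_too_few_samples_rejected(self, trained_stack, dev_ext):
        _, ext = dev_ext
        with pytest.raises(ValueError):
            attribute_base_models(trained_stack, ext.head(3))


class TestSampledShapley:
    def test_three_feature_toy_matches_enumeration(self):
        import pandas as pd

        coef = np.array([1.5, -2.0, 0.7])

        def predict(df):
            z = df[["a", "b", "c"]].to_numpy(dtype=float) @ coef
            return 1.0 / (1.0 + np.exp(-z))

        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (6, 3)), columns=["a", "b", "c"])
        bg = X.iloc[[0]]
        phi, se = sampled_shapley(predict, X, bg, n_permutations=300, seed=1)

        bg_vec = bg.to_numpy(dtype=float)[0]
        for i in range(len(X)):
            def value(v):
                return float(1.0 / (1.0 + np.exp(-(v @ coef))))
            exact = exact_shapley(value, X.iloc[i].to_numpy(dtype=float),
                                  bg_vec.copy())
            assert np.all(np.abs(phi[i] - exact) <= 4 * se[i] + 1e-3)

    def test_null_feature_gets_negligible_share(self, trained_stack, dev_ext):
        dev, ext = dev_ext
        report = attribute_features(trained_stack, ext.head(25), dev.head(60),
                                    n_permutations=16, seed=2)
        assert report.percent.sum() == pytest.approx(100.0, abs=0.1)
        # planted nulls (e.g. vacuole) should rank far below the main signal
        shares = dict(zip(report.entities, report.percent))
        assert shares["ith3d"] > shares["vacuole"]

    def test_empty_background_rejected(self, trained_stack, dev_ext):
        _, ext = dev_ext
        with pytest.raises(ValueError):
            attribute_features(trained_stack, ext.head(12), ext.head(0))


class TestAblation:
    def test_stopping_rule_on_reference_trace(self):
        assert stopping_step([0.70, 0.75, 0.752, 0.751], 0.005) == 2
        assert stopping_step([0.6, 0.7, 0.8], 0.005) == 3
        assert stopping_step([0.9], 0.005) == 1

    def test_step_k_uses_top_k_features(self, dev_ext):
        from ith3d.ensemble import PipelineConfig

        dev, ext = dev_ext
        ranking = ["ith3d", "size_mm", "density"]
        cfg = PipelineConfig(seed=3, grids={"rf": {"n_estimators": [30]}})
        trace = shap_ablation(dev, ext, ranking, tolerance=0.005, config=cfg)
        assert [s["feature_set"] for s in trace.steps] == [
            ["ith3d"], ["ith3d", "size_mm"], ["ith3d", "size_mm", "density"]]
        assert 1 <= trace.stopping_step <= 3
        assert trace.selected_features == ranking[: trace.stopping_step]

    def test_negative_tolerance_rejected(self, dev_ext):
        dev, ext = dev_ext
        with pytest.raises(ValueError):
            shap_ablation(dev, ext, ["ith3d"], tolerance=-0.1)
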