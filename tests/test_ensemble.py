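"""Stacking pipeline: tuning, OOF meta-features, prediction, comparators."""

import pickle

import numpy as np
import pandas as pd
import pytest

from ith3d.cohorts import CohortSpec, make_cohort, split_cohort
from ith3d.ensemble import (
    PipelineConfig,
    SchemaError,
    build_meta_features,
    fast_grids,
    fit_base_models,
    fit_meta_classifier,
    run_comparator,
    select_radiomics_signature,
    train_stack,
)


class TestBaseModels:
    def test_single_point_grid_is_selected_and_reported(self, dev_ext, fast_config):
        dev, _ = dev_ext
        fitted = fit_base_models(dev, fast_config)
        assert sorted(fitted) == ["adaboost", "gbdt", "histgb", "lightgbm",
                                  "rf", "xgboost"]
        for fb in fitted.values():
            assert len(fb.cv_report) == 1
            assert fb.best_params == fb.cv_report[0]["params"]
            assert 0.0 <= fb.mean_cv_auc <= 1.0

    def test_separable_outcome_reaches_cv_auc_one(self, fast_config):
        table = make_cohort(CohortSpec(n=300, seed=31, effects={}))
        table["vpi"] = (table["ith3d"] > table["ith3d"].median()).astype(int)
        cfg = PipelineConfig(seed=1, grids={"rf": fast_grids()["rf"]},
                             balance="none")
        fitted = fit_base_models(table, cfg)
        assert fitted["rf"].mean_cv_auc > 0.99


class TestMetaFeatures:
    def test_oof_matrix_contract(self, dev_ext, fast_config, trained_stack):
        dev, _ = dev_ext
        M = trained_stack.oof_matrix
        assert M.shape == (len(dev), 6)
        assert ((M >= 0) & (M <= 1)).all()

    def test_identically_configured_learners_give_identical_columns(self, dev_ext):
        dev, _ = dev_ext
        cfg = PipelineConfig(seed=5, grids={
            "rf": {"n_estimators": [40], "max_depth": [4]},
            "xgboost": {"n_estimators": [40], "max_depth": [3]},
        })
        fitted = fit_base_models(dev, cfg)
        M1 = build_meta_features(dev, fitted, cfg)
        M2 = build_meta_features(dev, fitted, cfg)
        assert np.array_equal(M1, M2)

    def test_meta_classifier_on_perfect_feature(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 400)
        M = np.column_stack([y * 0.8 + 0.1] +
                            [rng.random(400) for _ in range(5)])
        meta, _ = fit_meta_classifier(M, y, folds=5)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, meta.predict_proba(M)[:, 1]) > 0.99

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_meta_classifier(np.random.rand(50, 6), np.zeros(50))


class TestPredict:
    def test_probabilities_in_unit_interval(self, trained_stack, dev_ext):
        _, ext = dev_ext
        p = trained_stack.predict_proba(ext)
        assert ((p >= 0) & (p <= 1)).all()

    def test_threshold_extremes(self, trained_stack, dev_ext):
        _, ext = dev_ext
        assert trained_stack.predict(ext, threshold=0.0).all()
        assert not trained_stack.predict(ext, threshold=1.0 + 1e-9).any()

    def test_monotone_in_positively_weighted_meta_feature(self, trained_stack):
        coefs = trained_stack.meta.coef_[0]
        j = int(np.argmax(coefs))
        assert coefs[j] > 0
        base = np.full((1, 6), 0.5)
        lo = trained_stack.meta.predict_proba(base)[0, 1]
        hi_row = base.copy()
        hi_row[0, j] = 0.9
        hi = trained_stack.meta.predict_proba(hi_row)[0, 1]
        assert hi > lo

    def test_schema_mismatch_raises(self, trained_stack, dev_ext):
        _, ext = dev_ext
        with pytest.raises(SchemaError):
            trained_stack.predict_proba(ext.drop(columns=["ith3d"]))


class TestLeakageAndDeterminism:
    def test_external_rows_never_touch_the_fit(self, cohort600, fast_config):
        dev_a, ext = split_cohort(cohort600)
        model_a = train_stack(dev_a, fast_config)
        # drop external rows from the cohort; development rows are identical
        drop_ids = set(ext["patient_id"].iloc[: len(ext) // 2])
        pruned = cohort600[~cohort600["patient_id"].isin(drop_ids)]
        dev_b, _ = split_cohort(pruned.reset_index(drop=True))
        model_b = train_stack(dev_b.reset_index(drop=True), fast_config)
        assert pickle.dumps(model_a.meta) == pickle.dumps(model_b.meta)
        assert np.array_equal(model_a.oof_matrix, model_b.oof_matrix)

    def test_end_to_end_reproducibility(self, dev_ext, fast_config):
        dev, ext = dev_ext
        a = train_stack(dev, fast_config)
        b = train_stack(dev, fast_config)
        assert np.array_equal(a.oof_matrix, b.oof_matrix)
        assert np.array_equal(a.predict_proba(ext), b.predict_proba(ext))


class TestComparators:
    def test_clinicoradiologic_variant_excludes_ith_scores(self, dev_ext, fast_config):
        dev, _ = dev_ext
        model = run_comparator(dev, "clinicoradiologic", fast_config)
        assert "ith3d" not in model.config.feature_cols
        assert "ith2d" not in model.config.feature_cols

    def test_radiomics_selection_stages(self):
        rng = np.random.default_rng(42)
        n, p = 400, 40
        X = rng.normal(0, 1, (n, p))
        X[:, 1] = X[:, 0]                       # duplicated feature, r = 1
        y = (X[:, 0] + X[:, 2] + X[:, 4] + rng.normal(0, 1.0, n) > 0).astype(int)
        X[:, 5] = rng.normal(0, 1, n)           # pure noise
        feats = pd.DataFrame(X, columns=[f"r{i}" for i in range(p)])
        sig = select_radiomics_signature(feats, y, p_remove=0.5, seed=0)
        # of the duplicated pair only the first column survives pruning
        assert "r0" in sig.correlation_kept and "r1" not in sig.correlation_kept
        assert set(sig.selected) <= set(sig.correlation_kept)
        assert len(sig.selected) >= 1
        p_out = sig.predict_proba(feats)
        assert ((p_out >= 0) & (p_out <= 1)).all()

    def test_feature_identical_across_groups_is_removed(self):
        rng = np.random.default_rng(1)
        n = 200
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({
            "informative": y + rng.normal(0, 0.5, n),
            "flat": np.ones(n) * 3.3 + np.where(y == 1, 0.0, 0.0),
        })
        # identical distribution across groups -> t-test keeps it only if
        # P <= threshold; a strictly constant column has P = nan -> removed
        sig = select_radiomics_signature(X, y, p_remove=0.5, seed=0)
        assert "flat" not in sig.ttest_kept

    def test_missing_feature_table_rejected(self, dev_ext, fast_config):
        dev, _ = dev_ext
        with pytest.raises(SchemaError):
            run_comparator(dev, "radiomics_signature", fast_config)
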