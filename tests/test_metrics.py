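"""Evaluation metrics, decision curves and the leave-one-center-out harness."""

import numpy as np
import pytest

from _oracles import pairwise_auc, pr_auc_sweep
from ith3d.metrics import (
    decision_curve,
    evaluate,
    loco_validate,
    pr_auc,
    roc_auc,
    threshold_metrics,
)


class TestRocAuc:
    def test_four_point_example(self):
        auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 10, [0, 1] * 5)
        assert auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # rounding forces ties
            auc, _ = roc_auc(s, y)
            assert auc == pytest.approx(pairwise_auc(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 60)
        y[:5] = 1
        y[5:10] = 0
        s = rng.random(60)
        a1, _ = roc_auc(s, y)
        a2, _ = roc_auc(np.exp(3 * s) + 7, y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestPrAuc:
    def test_perfect_ranking(self):
        ap, _ = pr_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert ap == 1.0

    def test_toy_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                continue
            s = rng.random(n)
            ap, _ = pr_auc(s, y)
            assert ap == pytest.approx(pr_auc_sweep(s, y), abs=1e-12)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(3)
        y = (rng.random(5000) < 0.134).astype(int)
        ap, _ = pr_auc(rng.random(5000), y)
        assert ap == pytest.approx(0.134, abs=0.03)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.5, 0.6], [0, 0])


class TestThresholdMetrics:
    def test_hand_computed_confusion(self):
        # TP=3, FP=2, FN=1, TN=4
        scores = [0.9, 0.8, 0.7, 0.6, 0.55, 0.2, 0.3, 0.1, 0.4, 0.05]
        labels = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        m = threshold_metrics(scores, labels, threshold=0.5)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (3, 2, 1, 4)
        assert m["precision"] == pytest.approx(0.6)
        assert m["recall"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_zero_threshold_has_full_recall(self):
        m = threshold_metrics([0.1, 0.9, 0.4], [1, 1, 0], threshold=0.0)
        assert m["recall"] == 1.0

    def test_no_predicted_positives_flagged(self):
        m = threshold_metrics([0.1, 0.2], [1, 0], threshold=0.9)
        assert m["precision"] == 0.0
        assert "no_predicted_positives" in m["flags"]

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_metrics([0.5], [1], threshold=1.5)


class TestDecisionCurve:
    def test_treat_all_closed_form(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        nb = decision_curve(rng.random(200), y)
        prev = y.mean()
        expected = prev - (1 - prev) * nb["threshold"] / (1 - nb["threshold"])
        assert np.allclose(nb["treat_all"], expected)

    def test_perfect_classifier_attains_prevalence(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        nb = decision_curve(y.astype(float), y)
        assert np.allclose(nb["net_benefit"], y.mean())

    def test_direct_substitution_example(self):
        # n=10, TP=3, FP=2 at p_t=0.2 -> 0.3 - 0.2 * 0.25 = 0.25
        scores = [0.9, 0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1]
        labels = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        nb = decision_curve(scores, labels, thresholds=[0.2])
        assert nb["net_benefit"].iloc[0] == pytest.approx(0.25)

    def test_net_benefit_never_exceeds_prevalence(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 300)
        nb = decision_curve(rng.random(300), y)
        assert (nb["net_benefit"] <= y.mean() + 1e-12).all()

    def test_degenerate_threshold_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[1.0])


class TestEvaluateAndLoco:
    def test_report_internally_consistent(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 150)
        y[:3] = 1
        y[3:6] = 0
        s = np.clip(y * 0.4 + rng.random(150) * 0.6, 0, 1)
        rep = evaluate(s, y, threshold=0.5)
        assert sum(rep.confusion.values()) == 150
        assert 0 <= rep.auc <= 1 and 0 <= rep.pr_auc <= 1
        assert rep.cohort["n"] == 150

    def test_each_center_held_out_once(self, cohort600, fast_config):
        from dataclasses import replace

        cfg = replace(fast_config, grids={"rf": {"n_estimators": [30]}})
        reports = loco_validate(cohort600, cfg)
        assert sorted(reports) == [1, 2, 3]
        for c, rep in reports.items():
            assert rep.cohort["center"] == c
            assert rep.cohort["n"] == (cohort600["center"] == c).sum()

    def test_single_class_center_flagged(self, cohort600, fast_config):
        from dataclasses import replace

        table = cohort600.copy()
        table.loc[table["center"] == 2, "vpi"] = 0
        cfg = replace(fast_config, grids={"rf": {"n_estimators": [30]}})
        reports = loco_validate(table, cfg)
        assert "single_class_center" in reports[2].flags
        assert np.isnan(reports[2].auc)

    def test_fewer_than_two_centers_rejected(self, cohort600):
        table = cohort600.copy()
        table["center"] = 1
        with pytest.raises(ValueError):
            loco_validate(table)
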