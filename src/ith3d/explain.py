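"""Additive attribution of base-model and feature contributions, plus the
attribution-guided stepwise-addition ablation.

For the linear (logistic) meta-classifier the Shapley value of meta-feature
j on the linear-predictor scale is exact and closed-form:
``phi_j = coef_j * (x_j - E[x_j])`` with the expectation over a background
set.  For input features of the end-to-end stack, Shapley values are
estimated model-agnostically by permutation sampling against background
rows, with a Monte-Carlo standard error reported.

The ablation retrains the stack on the top-k ranked features for growing k,
recording mean CV AUC and external AUC per step, and flags the first step
whose external-AUC improvement falls below a plateau tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .ensemble import PipelineConfig, StackedModel, train_stack


@dataclass
class AttributionReport:
    """Per-entity additive attributions with normalized percent shares."""

    entities: list[str]
    mean_abs: np.ndarray
    percent: np.ndarray               # sums to 100
    ranking: list[str]                # descending mean |attribution|
    matrix: np.ndarray                # (samples, entities) attribution values
    standard_error: np.ndarray | None = None
    background: str = ""


def _report(entities, matrix, se=None, background=""):
    mean_abs = np.abs(matrix).mean(axis=0)
    total = mean_abs.sum()
    percent = 100.0 * mean_abs / total if total > 0 else np.full_like(mean_abs, 0.0)
    order = np.argsort(-mean_abs, kind="stable")
    return AttributionReport(
        entities=list(entities), mean_abs=mean_abs, percent=percent,
        ranking=[entities[i] for i in order], matrix=matrix,
        standard_error=se, background=background)


def attribute_base_models(model: StackedModel, samples: pd.DataFrame,
                          background: pd.DataFrame | None = None) -> AttributionReport:
    """Exact Shapley attribution of the six base models in the meta-classifier.

    The meta-classifier is linear in the meta-features, so the attribution
    of base model j for a sample is its coefficient times the centred
    meta-feature (centred on the background mean) — identical to exhaustive
    subset enumeration for a linear value function.
    """
    if not hasattr(model.meta, "coef_"):
        raise ValueError("stack is not fitted")
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to attribute")
    M = model.meta_features(samples)
    Mb = model.meta_features(background) if background is not None else M
    phi = model.meta.coef_[0][None, :] * (M - Mb.mean(axis=0)[None, :])
    return _report(model.learner_order, phi,
                   background=f"{len(Mb)} rows (meta-feature means)")


def sampled_shapley(predict_fn, X: pd.DataFrame, background: pd.DataFrame,
                    n_permutations: int = 64, seed: int = 0,
                    feature_cols: list[str] | None = None):
    """Permutation-sampling Shapley estimates for a black-box predictor.

    For each evaluated row, random feature orderings are walked; each
    feature's marginal contribution is the change in prediction when its
    value switches from a background row's to the evaluated row's.  Returns
    ``(phi, se)`` with shape (rows, features).
    """
    if len(background) == 0:
        raise ValueError("background set is empty")
    cols = feature_cols if feature_cols is not None else list(X.columns)
    rng = np.random.default_rng(seed)
    n, k = len(X), len(cols)
    phi = np.zeros((n, k))
    phi2 = np.zeros((n, k))
    for _ in range(n_permutations):
        order = rng.permutation(k)
        bg = background.iloc[rng.integers(len(background), size=n)].reset_index(drop=True)
        current = bg.copy()
        for c in X.columns:
            if c not in cols:
                current[c] = X[c].to_numpy()
        prev = predict_fn(current)
        for j in order:
            current[cols[j]] = X[cols[j]].to_numpy()
            nxt = predict_fn(current)
            contrib = nxt - prev
            phi[:, j] += contrib
            phi2[:, j] += contrib ** 2
            prev = nxt
    phi /= n_permutations
    var = phi2 / n_permutations - phi ** 2
    se = np.sqrt(np.maximum(var, 0.0) / n_permutations)
    return phi, se


def attribute_features(model: StackedModel, samples: pd.DataFrame,
                       background: pd.DataFrame, n_permutations: int = 64,
                       seed: int = 0) -> AttributionReport:
    """Sampling-based Shapley attribution of the stack's input features."""
    cols = model.config.feature_cols
    phi, se = sampled_shapley(model.predict_proba, samples, background,
                              n_permutations=n_permutations, seed=seed,
                              feature_cols=cols)
    return _report(cols, phi, se=se, background=f"{len(background)} training rows")


@dataclass
class AblationTrace:
    """Stepwise feature-addition trace with the plateau stopping step."""

    ranking: list[str]
    steps: list[dict] = field(default_factory=list)  # feature_set, cv_auc, external_auc
    stopping_step: int = 0
    tolerance: float = 0.005

    @property
    def selected_features(self) -> list[str]:
        return list(self.steps[self.stopping_step - 1]["feature_set"])


def shap_ablation(dev_table: pd.DataFrame, external_table: pd.DataFrame,
                  ranking: list[str], tolerance: float = 0.005,
                  config: PipelineConfig | None = None) -> AblationTrace:
    """Stepwise feature addition in attribution order with plateau stopping.

    Step k trains the stack on the top-k ranked features; the external AUC
    trace is scanned for the first step improving the previous one by less
    than ``tolerance`` — the step before it is the stopping step.  The full
    trace is always returned for plotting.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    config = config or PipelineConfig()
    y_ext = external_table[config.outcome_col].to_numpy()
    trace = AblationTrace(ranking=list(ranking), tolerance=tolerance)
    from dataclasses import replace
    for k in range(1, len(ranking) + 1):
        feats = list(ranking[:k])
        cfg = replace(config, feature_cols=feats)
        model = train_stack(dev_table, cfg)
        cv_auc = float(np.mean([fb.mean_cv_auc for fb in model.base.values()]))
        ext_auc = float(roc_auc_score(y_ext, model.predict_proba(external_table)))
        trace.steps.append({"feature_set": feats, "cv_auc": cv_auc,
                            "external_auc": ext_auc})
    trace.stopping_step = stopping_step(
        [s["external_auc"] for s in trace.steps], tolerance)
    return trace


def stopping_step(auc_trace, tolerance: float = 0.005) -> int:
    """First step (1-based) after which the AUC improvement falls below tolerance."""
    for i in range(1, len(auc_trace)):
        if auc_trace[i] - auc_trace[i - 1] < tolerance:
            return i
    return len(auc_trace)
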