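"""Stacking-ensemble pipeline over clinicoradiologic + ITH features.

Six base learners — AdaBoost, gradient-boosted trees (GBDT), histogram
gradient boosting, LightGBM, random forest and XGBoost — are tuned by
grid-searched stratified 5-fold cross-validation maximising AUC, with
class balancing (SMOTE + Tomek) applied inside each fold's training split
only.  Their out-of-fold probabilities form a 6-column meta-feature matrix
on which a logistic-regression meta-classifier is fitted (its C likewise
grid-searched by CV AUC).  External rows never influence any fit.

Meta-feature columns are ordered alphabetically by learner name so runs
are comparable.  Categorical inputs are one-hot encoded for every learner
except histogram gradient boosting, which consumes native category codes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from lightgbm import LGBMClassifier
from xgboost import XGBClassifier

from .cohorts import ALL_FEATURES, CATEGORICAL_FEATURES
from .resampling import smote_tomek

#: fixed meta-feature column order
LEARNER_ORDER = ["adaboost", "gbdt", "histgb", "lightgbm", "rf", "xgboost"]

# lightgbm's sklearn wrapper records synthetic column names and then warns on
# every plain-array predict; the design matrix is positional by construction
warnings.filterwarnings("ignore", message="X does not have valid feature names")


class SchemaError(ValueError):
    """Prediction table does not match the training schema."""


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TablePreprocessor:
    """Encode a cohort table as a numeric design matrix.

    Continuous/binary columns are z-scored with training statistics;
    categorical columns are one-hot coded, or kept as native category codes
    (with a categorical mask) for learners that handle them directly.
    """

    def __init__(self, feature_cols, categorical_cols=None, native_categorical=False):
        self.feature_cols = list(feature_cols)
        self.categorical_cols = [c for c in (categorical_cols or CATEGORICAL_FEATURES)
                                 if c in self.feature_cols]
        self.native_categorical = native_categorical

    def fit(self, table: pd.DataFrame) -> "TablePreprocessor":
        self.levels_ = {c: np.unique(table[c].to_numpy()) for c in self.categorical_cols}
        self.stats_ = {}
        for c in self.feature_cols:
            if c not in self.categorical_cols:
                v = table[c].to_numpy(dtype=float)
                self.stats_[c] = (v.mean(), v.std() if v.std() > 1e-12 else 1.0)
        self.columns_ = []
        mask = []
        for c in self.feature_cols:
            if c in self.categorical_cols and not self.native_categorical:
                self.columns_ += [f"{c}={lv}" for lv in self.levels_[c]]
                mask += [False] * len(self.levels_[c])
            else:
                self.columns_.append(c)
                mask.append(c in self.categorical_cols)
        self.categorical_mask_ = np.array(mask)
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_cols if c not in table.columns]
        if missing:
            raise SchemaError(f"table lacks required columns: {missing}")
        blocks = []
        for c in self.feature_cols:
            v = table[c].to_numpy(dtype=float)
            if c in self.categorical_cols:
                if self.native_categorical:
                    blocks.append(v[:, None])
                else:
                    blocks.append((v[:, None] == self.levels_[c][None, :]).astype(float))
            else:
                mu, sd = self.stats_[c]
                blocks.append(((v - mu) / sd)[:, None])
        return np.hstack(blocks)

    def fit_transform(self, table: pd.DataFrame) -> np.ndarray:
        return self.fit(table).transform(table)


# ---------------------------------------------------------------------------
# learners and grids
# ---------------------------------------------------------------------------

def make_learner(name: str, params: dict, seed: int,
                 categorical_mask: np.ndarray | None = None):
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if name == "gbdt":
        return GradientBoostingClassifier(random_state=seed, **params)
    if name == "histgb":
        mask = categorical_mask if categorical_mask is not None else None
        return HistGradientBoostingClassifier(
            random_state=seed, categorical_features=mask, **params)
    if name == "lightgbm":
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
    if name == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "xgboost":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss", **params)
    raise ValueError(f"unknown learner {name!r}")


def default_grids() -> dict[str, dict[str, list]]:
    """Small documented hyperparameter grids (3-4 points per learner)."""
    return {
        "adaboost": {"n_estimators": [50, 100, 200]},
        "gbdt": {"n_estimators": [100, 200], "max_depth": [2, 3]},
        "histgb": {"max_iter": [100, 200], "max_depth": [None, 3]},
        "lightgbm": {"n_estimators": [100, 200], "num_leaves": [15, 31]},
        "rf": {"n_estimators": [200], "max_depth": [None, 4, 8]},
        "xgboost": {"n_estimators": [100, 200], "max_depth": [2, 4]},
    }


def fast_grids() -> dict[str, dict[str, list]]:
    """Single-point grids with small learners, for quick experiments."""
    return {
        "adaboost": {"n_estimators": [30]},
        "gbdt": {"n_estimators": [60], "max_depth": [2]},
        "histgb": {"max_iter": [60]},
        "lightgbm": {"n_estimators": [60], "num_leaves": [15]},
        "rf": {"n_estimators": [60], "max_depth": [6]},
        "xgboost": {"n_estimators": [60], "max_depth": [3]},
    }


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


@dataclass
class PipelineConfig:
    """Everything the training pipeline needs, with conventional defaults."""

    feature_cols: list[str] = field(default_factory=lambda: list(ALL_FEATURES))
    outcome_col: str = "vpi"
    folds: int = 5
    seed: int = 42
    balance: str = "smotetomek"          # "smotetomek" | "none"
    k_neighbors: int = 5
    grids: dict = field(default_factory=default_grids)
    meta_C_grid: tuple = (0.01, 0.1, 1.0, 10.0)
    threshold: float = 0.5


@dataclass
class FittedBase:
    """One tuned base learner with its selection report."""

    name: str
    best_params: dict
    cv_report: list[dict]                # per grid point: params + mean AUC
    mean_cv_auc: float
    model: object
    preprocessor: TablePreprocessor


@dataclass
class StackedModel:
    """Fitted stacking ensemble: six base learners + logistic meta-classifier."""

    base: dict[str, FittedBase]
    meta: LogisticRegression
    meta_C: float
    oof_matrix: np.ndarray
    train_outcome: np.ndarray
    config: PipelineConfig

    @property
    def learner_order(self) -> list[str]:
        return sorted(self.base)

    def meta_features(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.learner_order:
            fb = self.base[name]
            X = fb.preprocessor.transform(table)
            cols.append(fb.model.predict_proba(X)[:, 1])
        return np.column_stack(cols)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return self.meta.predict_proba(self.meta_features(table))[:, 1]

    def predict(self, table: pd.DataFrame, threshold: float | None = None) -> np.ndarray:
        thr = self.config.threshold if threshold is None else threshold
        return (self.predict_proba(table) >= thr).astype(int)


# ---------------------------------------------------------------------------
# training stages
# ---------------------------------------------------------------------------

def balance_training(table: pd.DataFrame, method: str = "smotetomek",
                     k_neighbors: int = 5, seed: int = 0,
                     outcome_col: str = "vpi",
                     feature_cols: list[str] | None = None) -> pd.DataFrame:
    """Apply the configured class balancing to a training table."""
    if method == "none":
        return table
    if method != "smotetomek":
        raise ValueError(f"unknown balancing method {method!r}")
    return smote_tomek(table, outcome_col=outcome_col, feature_cols=feature_cols,
                       k_neighbors=k_neighbors, seed=seed)


def _fold_iter(table: pd.DataFrame, config: PipelineConfig):
    y = table[config.outcome_col].to_numpy()
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    yield from skf.split(np.zeros(len(y)), y)


def _fit_on(table: pd.DataFrame, name: str, params: dict, config: PipelineConfig,
            seed: int) -> tuple[object, TablePreprocessor]:
    native = name == "histgb"
    prep = TablePreprocessor(config.feature_cols,
                             native_categorical=native).fit(table)
    model = make_learner(name, params, seed,
                         categorical_mask=prep.categorical_mask_ if native else None)
    X = prep.transform(table)
    y = table[config.outcome_col].to_numpy()
    model.fit(X, y)
    return model, prep


def fit_base_models(table: pd.DataFrame, config: PipelineConfig | None = None,
                    ) -> dict[str, FittedBase]:
    """Grid-search each base learner by stratified CV AUC and refit on all rows.

    Balancing, when enabled, happens inside each fold's training split only,
    so validation folds are untouched.  Ties in mean CV AUC resolve to the
    earliest grid point.
    """
    config = config or PipelineConfig()
    y_all = table[config.outcome_col].to_numpy()
    folds = list(_fold_iter(table, config))
    fitted: dict[str, FittedBase] = {}
    for name in sorted(config.grids):
        points = _grid_points(config.grids[name])
        report = []
        for params in points:
            aucs = []
            for fi, (tr, va) in enumerate(folds):
                tr_tab = balance_training(
                    table.iloc[tr], config.balance, config.k_neighbors,
                    seed=config.seed + fi, outcome_col=config.outcome_col,
                    feature_cols=config.feature_cols)
                model, prep = _fit_on(tr_tab, name, params, config, config.seed)
                proba = model.predict_proba(prep.transform(table.iloc[va]))[:, 1]
                aucs.append(roc_auc_score(y_all[va], proba))
            report.append({"params": params, "mean_auc": float(np.mean(aucs))})
        best_i = int(np.argmax([r["mean_auc"] for r in report]))  # first max wins
        best = report[best_i]
        full_tab = balance_training(table, config.balance, config.k_neighbors,
                                    seed=config.seed, outcome_col=config.outcome_col,
                                    feature_cols=config.feature_cols)
        model, prep = _fit_on(full_tab, name, best["params"], config, config.seed)
        fitted[name] = FittedBase(name=name, best_params=best["params"],
                                  cv_report=report, mean_cv_auc=best["mean_auc"],
                                  model=model, preprocessor=prep)
    return fitted


def build_meta_features(table: pd.DataFrame, fitted: dict[str, FittedBase],
                        config: PipelineConfig | None = None) -> np.ndarray:
    """Out-of-fold probabilities for every training row and base learner.

    Each row's prediction comes from models trained without that row's fold;
    columns follow the alphabetical learner order.
    """
    config = config or PipelineConfig()
    n = len(table)
    order = sorted(fitted)
    M = np.full((n, len(order)), np.nan)
    for tr, va in _fold_iter(table, config):
        tr_tab = balance_training(
            table.iloc[tr], config.balance, config.k_neighbors,
            seed=config.seed + int(va[0]), outcome_col=config.outcome_col,
            feature_cols=config.feature_cols)
        for ci, name in enumerate(order):
            model, prep = _fit_on(tr_tab, name, fitted[name].best_params,
                                  config, config.seed)
            M[va, ci] = model.predict_proba(prep.transform(table.iloc[va]))[:, 1]
    assert not np.isnan(M).any()
    return M


def fit_meta_classifier(oof_matrix: np.ndarray, outcome: np.ndarray,
                        folds: int = 5, C_grid=(0.01, 0.1, 1.0, 10.0),
                        seed: int = 42) -> tuple[LogisticRegression, float]:
    """Tune and fit the logistic meta-classifier on the OOF matrix."""
    if len(np.unique(outcome)) < 2:
        raise ValueError("outcome is constant; cannot fit meta-classifier")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    mean_aucs = []
    for C in C_grid:
        aucs = []
        for tr, va in skf.split(oof_matrix, outcome):
            lr = LogisticRegression(C=C, max_iter=1000)
            lr.fit(oof_matrix[tr], outcome[tr])
            aucs.append(roc_auc_score(outcome[va],
                                      lr.predict_proba(oof_matrix[va])[:, 1]))
        mean_aucs.append(np.mean(aucs))
    best_C = C_grid[int(np.argmax(mean_aucs))]
    meta = LogisticRegression(C=best_C, max_iter=1000)
    meta.fit(oof_matrix, outcome)
    return meta, float(best_C)


def train_stack(table: pd.DataFrame, config: PipelineConfig | None = None) -> StackedModel:
    """End-to-end training: base tuning, OOF meta-features, meta-classifier."""
    config = config or PipelineConfig()
    fitted = fit_base_models(table, config)
    M = build_meta_features(table, fitted, config)
    y = table[config.outcome_col].to_numpy()
    meta, best_C = fit_meta_classifier(M, y, folds=config.folds,
                                       C_grid=config.meta_C_grid, seed=config.seed)
    return StackedModel(base=fitted, meta=meta, meta_C=best_C, oof_matrix=M,
                        train_outcome=y, config=config)


# ---------------------------------------------------------------------------
# comparator models
# ---------------------------------------------------------------------------

@dataclass
class RadiomicsSignature:
    """Logistic signature over LASSO-selected whole-lesion features."""

    selected: list[str]
    ttest_kept: list[str]
    correlation_kept: list[str]
    lasso_C: float
    model: LogisticRegression
    means: np.ndarray
    stds: np.ndarray

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.selected if c not in features.columns]
        if missing:
            raise SchemaError(f"feature table lacks columns: {missing}")
        X = (features[self.selected].to_numpy(dtype=float) - self.means) / self.stds
        return self.model.predict_proba(X)[:, 1]


def select_radiomics_signature(features: pd.DataFrame, outcome: np.ndarray,
                               p_remove: float = 0.5, r_max: float = 0.9,
                               folds: int = 10, seed: int = 42,
                               C_grid=None) -> RadiomicsSignature:
    """Three-stage selection: t-test filter, Pearson pruning, LASSO (1-SE).

    Features whose two-sample t-test P exceeds ``p_remove`` are dropped; of
    each pair with |Pearson r| > ``r_max`` the later column is dropped; an
    L1-penalised logistic model tuned by 10-fold CV deviance with the 1-SE
    rule keeps the final subset, on which a plain logistic signature is fit.
    """
    from scipy import stats

    cols = list(features.columns)
    X = features.to_numpy(dtype=float)
    y = np.asarray(outcome)

    _, pvals = stats.ttest_ind(X[y == 1], X[y == 0], axis=0, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)
    ttest_kept = [c for c, p in zip(cols, pvals) if p <= p_remove]
    if not ttest_kept:
        raise ValueError("t-test filter removed every feature")

    Xk = features[ttest_kept].to_numpy(dtype=float)
    corr = np.corrcoef(Xk, rowvar=False)
    keep_idx = []
    for j in range(len(ttest_kept)):
        if all(abs(corr[j, i]) <= r_max for i in keep_idx):
            keep_idx.append(j)
    corr_kept = [ttest_kept[j] for j in keep_idx]

    Xc = features[corr_kept].to_numpy(dtype=float)
    means, stds = Xc.mean(axis=0), Xc.std(axis=0)
    stds[stds < 1e-12] = 1.0
    Xs = (Xc - means) / stds

    if C_grid is None:
        C_grid = np.logspace(-3, 1, 15)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev_mean, dev_se = [], []
    for C in C_grid:
        losses = []
        for tr, va in skf.split(Xs, y):
            lr = LogisticRegression(penalty="l1", solver="liblinear", C=C,
                                    max_iter=2000)
            lr.fit(Xs[tr], y[tr])
            losses.append(log_loss(y[va], lr.predict_proba(Xs[va])[:, 1],
                                   labels=[0, 1]))
        dev_mean.append(np.mean(losses))
        dev_se.append(np.std(losses) / np.sqrt(folds))
    i_min = int(np.argmin(dev_mean))
    # 1-SE rule: sparsest model within one SE of the minimum deviance
    cutoff = dev_mean[i_min] + dev_se[i_min]
    i_1se = next(i for i in range(len(C_grid)) if dev_mean[i] <= cutoff)
    lasso = LogisticRegression(penalty="l1", solver="liblinear",
                               C=float(C_grid[i_1se]), max_iter=2000)
    lasso.fit(Xs, y)
    nz = np.flatnonzero(lasso.coef_[0])
    if len(nz) == 0:  # fall back to the deviance minimiser
        lasso = LogisticRegression(penalty="l1", solver="liblinear",
                                   C=float(C_grid[i_min]), max_iter=2000)
        lasso.fit(Xs, y)
        nz = np.flatnonzero(lasso.coef_[0])
    selected = [corr_kept[j] for j in nz]

    Xf = features[selected].to_numpy(dtype=float)
    fmeans, fstds = Xf.mean(axis=0), Xf.std(axis=0)
    fstds[fstds < 1e-12] = 1.0
    final = LogisticRegression(max_iter=2000)
    final.fit((Xf - fmeans) / fstds, y)
    return RadiomicsSignature(selected=selected, ttest_kept=ttest_kept,
                              correlation_kept=corr_kept,
                              lasso_C=float(C_grid[i_1se]), model=final,
                              means=fmeans, stds=fstds)


def run_comparator(table: pd.DataFrame, variant: str,
                   config: PipelineConfig | None = None,
                   radiomics_features: pd.DataFrame | None = None):
    """Fit one of the comparative models on a development table.

    ``full`` and ``clinicoradiologic`` reuse the stacking pipeline (the
    latter without the ITH scores); ``radiomics_signature`` runs the
    three-stage selection on a per-patient whole-lesion feature table.
    """
    from .cohorts import CLINICORADIOLOGIC_FEATURES

    config = config or PipelineConfig()
    if variant == "full":
        return train_stack(table, config)
    if variant == "clinicoradiologic":
        cfg = replace(config,
                      feature_cols=[c for c in CLINICORADIOLOGIC_FEATURES
                                    if c in table.columns])
        return train_stack(table, cfg)
    if variant == "radiomics_signature":
        if radiomics_features is None:
            raise SchemaError("radiomics_signature needs a per-patient feature table")
        y = table[config.outcome_col].to_numpy()
        return select_radiomics_signature(radiomics_features, y,
                                          seed=config.seed)
    raise ValueError(f"unknown comparator variant {variant!r}")
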