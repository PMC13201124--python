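"""Discrimination metrics, decision-curve analysis and validation harnesses.

AUC is the pairwise concordance probability (ties count 1/2); PR-AUC uses
the step-interpolation convention (no linear interpolation between
operating points), under which random scores give PR-AUC ~ prevalence.
Net benefit at threshold probability p_t is ``TP/n - (FP/n) * p_t/(1-p_t)``;
the default grid 0.01..0.50 covers the range where the positive-class
prevalence stays below one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm


@dataclass
class EvalReport:
    """Threshold-free and threshold-based performance of one score vector."""

    auc: float
    pr_auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float
    confusion: dict                      # tp, fp, fn, tn
    roc_curve: tuple                     # (fpr, tpr, thresholds)
    pr_curve: tuple                      # (precision, recall, thresholds)
    net_benefit: pd.DataFrame | None = None
    cohort: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def roc_auc(scores, labels) -> tuple[float, tuple]:
    """AUC with its ROC curve; equals pairwise concordance with ties at 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    auc = float(skm.roc_auc_score(labels, scores))
    return auc, skm.roc_curve(labels, scores)


def pr_auc(scores, labels) -> tuple[float, tuple]:
    """Step-interpolated area under the precision-recall curve."""
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0:
        raise ValueError("need at least one positive for PR analysis")
    ap = float(skm.average_precision_score(labels, scores))
    return ap, skm.precision_recall_curve(labels, scores)


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Accuracy/precision/recall/F1 and confusion counts at one threshold.

    With zero predicted positives, precision is reported as 0 with a flag
    rather than raising.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    flags = []
    if tp + fp == 0:
        precision = 0.0
        flags.append("no_predicted_positives")
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    accuracy = (tp + tn) / len(labels)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "tp": tp, "fp": fp, "fn": fn, "tn": tn, "flags": flags}


def decision_curve(scores, labels, thresholds=None) -> pd.DataFrame:
    """Net-benefit curve with treat-all and treat-none references.

    ``net_benefit = TP/n - (FP/n) * p_t / (1 - p_t)`` per threshold
    probability p_t; p_t = 1 is excluded (the trade-off is undefined there).
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 0.505, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("threshold probabilities must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    prevalence = labels.mean()
    rows = []
    for pt in thresholds:
        pred = scores >= pt
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        odds = pt / (1 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit": tp / n - fp / n * odds,
            "treat_all": prevalence - (1 - prevalence) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def evaluate(scores, labels, threshold: float = 0.5,
             dca_thresholds=None, cohort: dict | None = None) -> EvalReport:
    """Full evaluation report for one score vector on one cohort."""
    auc, roc = roc_auc(scores, labels)
    ap, pr = pr_auc(scores, labels)
    tm = threshold_metrics(scores, labels, threshold)
    nb = decision_curve(scores, labels, dca_thresholds)
    labels = np.asarray(labels).astype(int)
    info = {"n": len(labels), "prevalence": float(labels.mean())}
    info.update(cohort or {})
    return EvalReport(
        auc=auc, pr_auc=ap, accuracy=tm["accuracy"], precision=tm["precision"],
        recall=tm["recall"], f1=tm["f1"], threshold=threshold,
        confusion={k: tm[k] for k in ("tp", "fp", "fn", "tn")},
        roc_curve=roc, pr_curve=pr, net_benefit=nb, cohort=info,
        flags=tm["flags"])


def loco_validate(table: pd.DataFrame, config=None, center_col: str = "center",
                  outcome_col: str = "vpi", threshold: float = 0.5) -> dict[int, EvalReport]:
    """Leave-one-center-out validation of the stacking pipeline.

    Each center is held out exactly once; training never sees held-out rows.
    A held-out center containing a single outcome class is flagged and its
    AUC omitted (reported as NaN).
    """
    from .ensemble import PipelineConfig, train_stack

    config = config or PipelineConfig()
    centers = sorted(table[center_col].unique())
    if len(centers) < 2:
        raise ValueError("need at least 2 centers for leave-one-center-out")
    reports: dict[int, EvalReport] = {}
    for c in centers:
        held = table[table[center_col] == c].reset_index(drop=True)
        rest = table[table[center_col] != c].reset_index(drop=True)
        model = train_stack(rest, config)
        proba = model.predict_proba(held)
        y = held[outcome_col].to_numpy()
        if len(np.unique(y)) < 2:
            tm = threshold_metrics(proba, y, threshold)
            reports[c] = EvalReport(
                auc=float("nan"), pr_auc=float("nan"),
                accuracy=tm["accuracy"], precision=tm["precision"],
                recall=tm["recall"], f1=tm["f1"], threshold=threshold,
                confusion={k: tm[k] for k in ("tp", "fp", "fn", "tn")},
                roc_curve=(), pr_curve=(),
                cohort={"center": c, "n": len(y), "prevalence": float(y.mean())},
                flags=tm["flags"] + ["single_class_center"])
        else:
            reports[c] = evaluate(proba, y, threshold, cohort={"center": c})
    return reports
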