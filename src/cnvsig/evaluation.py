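"""Benchmarking of multi-class CNV significance classifiers.

One-vs-rest PR and ROC curves per class (with the step-wise
average-precision estimator for PR AUC and trapezoidal ROC AUC), complement
scores for tools that only emit a pathogenicity score, harmonization of
5-level labels to the 3-class vocabulary, and multi-class summaries (per-class
F1, macro F1, accuracy, raw and row-normalized confusion matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    auc,
    average_precision_score,
    confusion_matrix,
    f1_score,
    precision_recall_curve,
    roc_curve,
)

from cnvsig.classifier import CLASS_ORDER

#: five-level prediction labels accepted by harmonize_labels
FIVE_LEVEL = ("benign", "likely benign", "VUS", "likely pathogenic", "pathogenic")


@dataclass
class CurveSet:
    """One-vs-rest curves and AUCs for a single positive class."""

    positive_class: str
    pr_auc: float
    roc_auc: float
    precision: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class EvaluationReport:
    curves: dict[str, CurveSet] = field(default_factory=dict)
    per_class_f1: dict[str, float] = field(default_factory=dict)
    macro_f1: float = float("nan")
    accuracy: float = float("nan")
    confusion: pd.DataFrame | None = None
    confusion_normalized: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "per_class_f1": self.per_class_f1,
            "curves": {
                cls: {"pr_auc": c.pr_auc, "roc_auc": c.roc_auc}
                for cls, c in self.curves.items()
            },
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.to_dict()
        return out


def one_vs_rest_curves(
    scores: Sequence[float], truth: Sequence[str], positive_class: str
) -> CurveSet:
    """PR and ROC curves ranking CNVs by the positive class's score.

    ROC AUC is the trapezoidal area (equivalently the Mann-Whitney pair
    statistic); PR AUC is the step-wise average-precision estimator, which
    avoids the optimism of linear interpolation in PR space. Tied scores are
    grouped into single threshold steps.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if t == positive_class else 0 for t in truth])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            f"need at least one positive and one negative for class {positive_class!r}"
        )
    precision, recall, _ = precision_recall_curve(y, scores)
    fpr, tpr, _ = roc_curve(y, scores)
    return CurveSet(
        positive_class=positive_class,
        pr_auc=float(average_precision_score(y, scores)),
        roc_auc=float(auc(fpr, tpr)),
        precision=precision,
        recall=recall,
        fpr=fpr,
        tpr=tpr,
    )


def complement_scores(pathogenic_scores: Sequence[float]) -> np.ndarray:
    """Benign-significance scores for single-score tools: 1 - Pr(pathogenic)."""
    return 1.0 - np.asarray(pathogenic_scores, dtype=float)


def harmonize_labels(labels: Sequence[str]) -> list[str]:
    """Map 5-level predictions onto the 3-class vocabulary.

    Likely-pathogenic collapses to pathogenic and likely-benign to benign so
    that 5-level tools compare fairly against 3-class ones.
    """
    mapping = {
        "benign": "benign",
        "likely benign": "benign",
        "likely_benign": "benign",
        "vus": "VUS",
        "uncertain significance": "VUS",
        "likely pathogenic": "pathogenic",
        "likely_pathogenic": "pathogenic",
        "pathogenic": "pathogenic",
    }
    out = []
    for lbl in labels:
        key = lbl.strip().lower() if lbl.strip().lower() != "vus" else "vus"
        if key not in mapping:
            raise ValueError(f"unknown prediction label {lbl!r}")
        out.append(mapping[key])
    return out


def multiclass_summary(
    predicted: Sequence[str],
    truth: Sequence[str],
    classes: Sequence[str] = CLASS_ORDER,
) -> EvaluationReport:
    """Per-class and macro F1, accuracy, and confusion matrices.

    The normalized confusion matrix divides each row by its actual-label
    total, so rows sum to 1 for observed classes.
    """
    predicted, truth = list(predicted), list(truth)
    if not truth:
        raise ValueError("empty evaluation input")
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    classes = list(classes)
    per_class = f1_score(truth, predicted, labels=classes, average=None, zero_division=0)
    cm = confusion_matrix(truth, predicted, labels=classes)
    row_totals = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm_norm = np.where(row_totals > 0, cm / np.maximum(row_totals, 1), 0.0)
    return EvaluationReport(
        per_class_f1={cls: float(s) for cls, s in zip(classes, per_class)},
        macro_f1=float(np.mean(per_class)),
        accuracy=float(accuracy_score(truth, predicted)),
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        confusion_normalized=pd.DataFrame(cm_norm, index=classes, columns=classes),
    )


def evaluate_probabilities(
    proba: np.ndarray,
    truth: Sequence[str],
    classes: Sequence[str] = CLASS_ORDER,
) -> EvaluationReport:
    """Full report from an (n, 3) probability matrix and true labels."""
    from cnvsig.classifier import label_from_probabilities

    proba = np.asarray(proba, dtype=float)
    predicted = [label_from_probabilities(p) for p in proba]
    report = multiclass_summary(predicted, truth, classes)
    for j, cls in enumerate(classes):
        present = any(t == cls for t in truth)
        if present and not all(t == cls for t in truth):
            report.curves[cls] = one_vs_rest_curves(proba[:, j], truth, cls)
    return report
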