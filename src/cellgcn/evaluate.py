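"""Classification metrics: accuracy, per-class precision/recall/F1 with their
medians, confusion matrices, and one-vs-rest ROC/AUC.

Rejected ("unassigned") cells are handled in both reporting modes: included
— they count as incorrect for accuracy and as false negatives for their true
class (never as false positives for any class) — or excluded before
computation, with the rejection rate reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .model import PredictionResult

UNASSIGNED = "unassigned"


@dataclass
class EvalReport:
    accuracy: float
    per_class: pd.DataFrame            # columns: class, precision, recall, f1, support
    median_f1: float
    median_precision: float
    median_recall: float
    confusion: pd.DataFrame            # rows true, columns predicted (+ unassigned)
    unassigned_rate: float = 0.0
    per_class_auc: dict[str, float] | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "accuracy": self.accuracy,
            "median_f1": self.median_f1,
            "median_precision": self.median_precision,
            "median_recall": self.median_recall,
            "unassigned_rate": self.unassigned_rate,
            "per_class": self.per_class.to_dict(orient="records"),
            "confusion": {
                "true_classes": list(self.confusion.index),
                "predicted_classes": list(self.confusion.columns),
                "counts": self.confusion.to_numpy().tolist(),
            },
            "per_class_auc": self.per_class_auc,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def per_class_tsv(self, path) -> None:
        self.per_class.to_csv(path, sep="\t", index=False)

    def confusion_tsv(self, path) -> None:
        self.confusion.to_csv(path, sep="\t")


def _as_prediction(predictions) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(predictions, PredictionResult):
        return predictions.predicted_labels, predictions.unassigned_mask
    pred = np.asarray(predictions, dtype=object)
    return pred, np.zeros(len(pred), dtype=bool)


def compute_metrics(true_labels, predictions, include_unassigned: bool = True,
                    classes: Sequence[str] | None = None) -> EvalReport:
    """Accuracy, per-class one-vs-rest precision/recall/F1 (0/0 -> 0), their
    medians, and the confusion matrix.

    ``predictions`` is a PredictionResult or a plain label array.  With
    ``include_unassigned=False`` rejected cells are removed first and only
    the rejection rate reflects them.
    """
    true_labels = np.asarray(true_labels, dtype=object)
    pred, rejected = _as_prediction(predictions)
    if len(true_labels) != len(pred):
        raise ValueError("true and predicted label counts differ")

    total_cells = len(true_labels)
    unassigned_rate = float(rejected.mean()) if total_cells else 0.0
    if not include_unassigned:
        keep = ~rejected
        true_labels, pred = true_labels[keep], pred[keep]
        rejected = np.zeros(len(pred), dtype=bool)

    if classes is None:
        classes = sorted({str(t) for t in true_labels} | {str(p) for p in pred})
    classes = [str(c) for c in classes]
    # effective prediction: rejected cells predict the reserved UNASSIGNED label
    eff = np.where(rejected, UNASSIGNED, pred.astype(str))
    true_s = true_labels.astype(str)

    pred_classes = classes + ([UNASSIGNED] if rejected.any() else [])
    conf = pd.DataFrame(0, index=classes, columns=pred_classes, dtype=int)
    for t, p in zip(true_s, eff):
        conf.loc[t, p] += 1

    rows = []
    for c in classes:
        tp = int(((true_s == c) & (eff == c)).sum())
        fp = int(((true_s != c) & (eff == c)).sum())
        fn = int(((true_s == c) & (eff != c)).sum())
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        rows.append({"class": c, "precision": precision, "recall": recall,
                     "f1": f1, "support": int((true_s == c).sum())})
    table = pd.DataFrame(rows)
    n = len(true_s)
    accuracy = float((true_s == eff).mean()) if n else 0.0
    return EvalReport(
        accuracy=accuracy,
        per_class=table,
        median_f1=float(table["f1"].median()) if len(table) else 0.0,
        median_precision=float(table["precision"].median()) if len(table) else 0.0,
        median_recall=float(table["recall"].median()) if len(table) else 0.0,
        confusion=conf,
        unassigned_rate=unassigned_rate,
    )


def roc_auc_per_class(true_labels, probabilities, classes: Sequence[str],
                      ) -> tuple[dict[str, float], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """One-vs-rest ROC per class from its probability column.

    AUC is the trapezoidal area; cells with tied scores move between
    confusion cells together (threshold grouping).  Classes lacking positives
    or negatives get a NaN AUC with a warning.  Returns (auc per class,
    (fpr, tpr) curve points per class).
    """
    true_labels = np.asarray(true_labels, dtype=object).astype(str)
    probabilities = np.atleast_2d(np.asarray(probabilities, dtype=float))
    if probabilities.shape != (len(true_labels), len(classes)):
        raise ValueError("probabilities shape does not match labels x classes")
    aucs: dict[str, float] = {}
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, c in enumerate(classes):
        y = (true_labels == str(c)).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            warnings.warn(f"class {c!r} has no positives or no negatives; AUC undefined",
                          stacklevel=2)
            aucs[str(c)] = float("nan")
            continue
        fpr, tpr, _ = _roc_curve(y, probabilities[:, j])
        aucs[str(c)] = float(_trapezoid_auc(fpr, tpr))
        curves[str(c)] = (fpr, tpr)
    return aucs, curves
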