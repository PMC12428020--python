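"""Confusion matrix, scalar metric suite and one-vs-rest ROC/AUC.

The multiclass confusion matrix (rows = true class, columns =
predicted) is reduced per class to one-vs-rest TP/FP/TN/FN counts,
from which the scalar suite follows: accuracy (in percent), and
per-class sensitivity, specificity, precision, NPV, FDR = 1 -
precision, F1, plus the balanced classification rate

    BCR = (1/C) sum_i (sensitivity_i + specificity_i) / 2.

Macro values are unweighted means over classes; a class with an
undefined denominator (e.g. no predicted positives) yields missing
per-class values that are excluded from the macro mean with a logged
note. ROC curves are one-vs-rest with trapezoidal AUC; curves are
stored as (FPR, TPR) points.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .data import CLASS_ORDER

logger = logging.getLogger(__name__)

PER_CLASS_METRICS = ("sensitivity", "specificity", "precision",
                     "npv", "fdr", "f1")


@dataclass
class ConfusionMatrix:
    """C x C counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_order = tuple(self.class_order)
        c = len(self.class_order)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square in the class order size")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred, class_order: tuple[str, ...] = CLASS_ORDER
              ) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    unknown = (set(y_true) | set(y_pred)) - set(class_order)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in class order")
    counts = _sk_confusion(y_true, y_pred, labels=list(class_order))
    return ConfusionMatrix(counts, class_order)


def one_vs_rest_counts(cm: ConfusionMatrix, class_i: int
                       ) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) of one class against the rest."""
    c = cm.counts
    if not 0 <= class_i < len(cm.class_order):
        raise ValueError("class index out of range")
    tp = int(c[class_i, class_i])
    fn = int(c[class_i].sum() - tp)
    fp = int(c[:, class_i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return tp, fp, tn, fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


@dataclass
class EvaluationReport:
    """Confusion matrix, the scalar metric suite, and ROC/AUC."""

    cm: ConfusionMatrix
    accuracy_percent: float
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    bcr: float
    roc: dict[str, dict] = field(default_factory=dict)  # class -> fpr/tpr/auc
    macro_auc: float = float("nan")
    micro_auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.cm.class_order),
            "confusion_matrix": self.cm.counts.tolist(),
            "accuracy_percent": self.accuracy_percent,
            "per_class": self.per_class,
            "macro": self.macro,
            "bcr": self.bcr,
            "roc": {
                cls: {"fpr": list(map(float, v["fpr"])),
                      "tpr": list(map(float, v["tpr"])),
                      "auc": float(v["auc"])}
                for cls, v in self.roc.items()
            },
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
            "averaging": "unweighted one-vs-rest macro",
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def scalar_metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """Accuracy, the six per-class rates, their macro means, and BCR."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * float(np.trace(cm.counts)) / cm.total
    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(cm.class_order):
        tp, fp, tn, fn = one_vs_rest_counts(cm, i)
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        prec = _safe_div(tp, tp + fp)
        npv = _safe_div(tn, fn + tn)
        fdr = 1.0 - prec if np.isfinite(prec) else float("nan")
        f1 = (_safe_div(2 * sens * prec, sens + prec)
              if np.isfinite(sens) and np.isfinite(prec) else float("nan"))
        per_class[cls] = {"sensitivity": sens, "specificity": spec,
                          "precision": prec, "npv": npv, "fdr": fdr, "f1": f1}
    macro: dict[str, float] = {}
    for metric in PER_CLASS_METRICS:
        vals = np.array([per_class[c][metric] for c in cm.class_order])
        if np.any(np.isnan(vals)):
            logger.warning("metric %s undefined for %d class(es); excluded "
                           "from the macro mean", metric,
                           int(np.isnan(vals).sum()))
        macro[metric] = float(np.nanmean(vals))
    bcr = float(np.mean([
        (per_class[c]["sensitivity"] + per_class[c]["specificity"]) / 2.0
        for c in cm.class_order
    ]))
    return EvaluationReport(cm=cm, accuracy_percent=accuracy,
                            per_class=per_class, macro=macro, bcr=bcr)


def roc_auc(per_class_scores: np.ndarray, y_true,
            class_order: tuple[str, ...] = CLASS_ORDER) -> dict:
    """One-vs-rest ROC per class plus macro (and pooled micro) AUC.

    ``per_class_scores`` is rows x classes with columns in
    ``class_order``. Thresholds sweep the sorted unique scores with
    ties grouped; AUC is trapezoidal. A class absent from ``y_true``
    has no ROC and is excluded from the macro mean.
    """
    scores = np.asarray(per_class_scores, dtype=np.float64)
    y_true = np.asarray(y_true)
    if scores.shape != (y_true.size, len(class_order)):
        raise ValueError("scores must be (n_rows, n_classes)")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    roc: dict[str, dict] = {}
    aucs = []
    pooled_true, pooled_score = [], []
    for j, cls in enumerate(class_order):
        binary = (y_true == cls).astype(int)
        pooled_true.append(binary)
        pooled_score.append(scores[:, j])
        if binary.sum() == 0 or binary.sum() == binary.size:
            logger.warning("class %s absent from one side of y_true; "
                           "ROC skipped", cls)
            continue
        fpr, tpr, _ = _sk_roc_curve(binary, scores[:, j])
        a = float(_trapezoid_auc(fpr, tpr))
        roc[cls] = {"fpr": fpr, "tpr": tpr, "auc": a}
        aucs.append(a)
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    pt = np.concatenate(pooled_true)
    ps = np.concatenate(pooled_score)
    if 0 < pt.sum() < pt.size:
        fpr, tpr, _ = _sk_roc_curve(pt, ps)
        micro_auc = float(_trapezoid_auc(fpr, tpr))
    else:  # pragma: no cover - degenerate single-class input
        micro_auc = float("nan")
    return {"per_class": roc, "macro_auc": macro_auc, "micro_auc": micro_auc}


def evaluate_predictions(y_true, y_pred, per_class_scores=None,
                         class_order: tuple[str, ...] = CLASS_ORDER
                         ) -> EvaluationReport:
    """Full report: confusion matrix, scalar suite, and (if scores are
    given) one-vs-rest ROC/AUC."""
    report = scalar_metrics(confusion(y_true, y_pred, class_order))
    if per_class_scores is not None:
        r = roc_auc(per_class_scores, y_true, class_order)
        report.roc = r["per_class"]
        report.macro_auc = r["macro_auc"]
        report.micro_auc = r["micro_auc"]
    return report
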