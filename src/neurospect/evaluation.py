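"""Report surface: 3x3 confusion matrix, per-class sensitivity/precision/
miss rate, overall accuracy, one-vs-rest ROC curves with trapezoid AUC, and
a combined summary table.

Rows of the confusion matrix are true classes, columns predicted classes,
in the fixed order 1 (MCI), 2 (AD), 3 (HC).  Percentages are reported to one
decimal with half-up rounding.  The multiclass ROC reduction is one-vs-rest
per class plus the macro-average AUC; tied scores are grouped at a single
threshold step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import CLASS_LABELS, CLASS_NAMES

_CLASSES = np.array(CLASS_LABELS)


class DegenerateRocError(ValueError):
    """ROC is undefined when only one class is present."""


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (72.25 -> 72.3 at one decimal)."""
    factor = 10.0**decimals
    return math.floor(value * factor + 0.5) / factor


def as_percent(fraction: float) -> float:
    """Fraction -> percentage with one-decimal half-up rounding."""
    return round_half_up(100.0 * fraction, 1)


@dataclass(frozen=True)
class ConfusionMatrix3:
    """Counts[i][j] = number of subjects with true class i+1 predicted j+1."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row(self, class_label: int) -> np.ndarray:
        return self.counts[class_label - 1]

    def column(self, class_label: int) -> np.ndarray:
        return self.counts[:, class_label - 1]


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix3:
    """Tally predictions into a 3x3 matrix (rows true, columns predicted)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and equal-length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.all(np.isin(arr, _CLASSES)):
            raise ValueError(f"{name} contains labels outside {CLASS_LABELS}")
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[int(t) - 1, int(p) - 1] += 1
    return ConfusionMatrix3(counts)


def sensitivity(cm: ConfusionMatrix3, class_label: int) -> float:
    """TP / (TP + FN): correct predictions over the true-class row sum."""
    row = cm.row(class_label)
    total = row.sum()
    if total == 0:
        raise ValueError(f"sensitivity undefined: no true class-{class_label} subjects")
    return float(row[class_label - 1] / total)


def precision(cm: ConfusionMatrix3, class_label: int) -> float:
    """TP over the predicted-class column sum."""
    col = cm.column(class_label)
    total = col.sum()
    if total == 0:
        raise ValueError(f"precision undefined: class {class_label} never predicted")
    return float(col[class_label - 1] / total)


def accuracy(cm: ConfusionMatrix3) -> float:
    """Trace over total count."""
    if cm.n == 0:
        raise ValueError("accuracy undefined on an empty matrix")
    return float(np.trace(cm.counts) / cm.n)


@dataclass(frozen=True)
class RocResult:
    """One-vs-rest ROC for one class: staircase points and trapezoid AUC."""

    class_label: int
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_one_vs_rest(y_true, scores, class_label: int) -> RocResult:
    """ROC of one class's score column against the rest.

    Thresholds sweep the distinct score values from above the maximum
    downward; TPR = TP/positives and FPR = FP/negatives at each step, with
    tied scores grouped at a single threshold.  AUC by the trapezoid rule.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape != (y_true.size, 3):
        raise ValueError("scores must be an (N x 3) matrix")
    if np.any(np.abs(scores.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("score rows must sum to 1")
    positive = y_true == class_label
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateRocError(
            f"need both positive and negative subjects for class {class_label}"
        )
    col = scores[:, class_label - 1]
    order = np.argsort(-col, kind="stable")
    sorted_scores = col[order]
    sorted_pos = positive[order].astype(np.int64)

    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(1 - sorted_pos)
    # keep only the last index of each tied-score run (grouped thresholds)
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(sorted_scores) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(class_label, thresholds, fpr, tpr, auc)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class and overall metrics, percentages to one decimal."""

    model_kind: str
    confusion: ConfusionMatrix3
    sensitivity_pct: dict[int, float]
    precision_pct: dict[int, float]
    miss_rate_pct: dict[int, float]
    accuracy_pct: float
    auc: dict[int, float]
    macro_auc: float

    def to_dict(self) -> dict:
        name = lambda c: CLASS_NAMES[c]  # noqa: E731
        return {
            "model": self.model_kind,
            "confusion_matrix": self.confusion.counts.tolist(),
            "sensitivity_pct": {name(c): v for c, v in self.sensitivity_pct.items()},
            "precision_pct": {name(c): v for c, v in self.precision_pct.items()},
            "miss_rate_pct": {name(c): v for c, v in self.miss_rate_pct.items()},
            "accuracy_pct": self.accuracy_pct,
            "auc": {name(c): v for c, v in self.auc.items()},
            "macro_auc": self.macro_auc,
        }


def summarize(cm: ConfusionMatrix3, rocs: dict[int, RocResult] | None,
              model_kind: str) -> EvaluationReport:
    """Assemble the per-model report row (sensitivity / precision / AUC /
    accuracy, plus miss rate = 100 - sensitivity)."""
    sens = {c: as_percent(sensitivity(cm, c)) for c in CLASS_LABELS}
    prec = {}
    for c in CLASS_LABELS:
        try:
            prec[c] = as_percent(precision(cm, c))
        except ValueError:
            prec[c] = float("nan")  # class never predicted
    miss = {c: round_half_up(100.0 - sens[c], 1) for c in CLASS_LABELS}
    aucs = {c: (rocs[c].auc if rocs and c in rocs else float("nan"))
            for c in CLASS_LABELS}
    finite = [v for v in aucs.values() if not math.isnan(v)]
    macro = float(np.mean(finite)) if finite else float("nan")
    return EvaluationReport(
        model_kind=model_kind,
        confusion=cm,
        sensitivity_pct=sens,
        precision_pct=prec,
        miss_rate_pct=miss,
        accuracy_pct=as_percent(accuracy(cm)),
        auc=aucs,
        macro_auc=macro,
    )


def evaluate_predictions(y_true, y_pred, scores, model_kind: str) -> EvaluationReport:
    """Confusion matrix + per-class ROC + summary in one call."""
    cm = confusion_matrix(y_true, y_pred)
    rocs = {}
    for c in CLASS_LABELS:
        try:
            rocs[c] = roc_one_vs_rest(y_true, scores, c)
        except DegenerateRocError:
            pass
    return summarize(cm, rocs, model_kind)
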