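"""Confusion-matrix bookkeeping and per-class diagnostic metrics with CIs.

Per class ``i`` the 6x6 confusion matrix (rows = true, columns = predicted)
is binarized one-vs-rest into TP/FP/TN/FN, from which

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)          (recall)
    specificity = TN / (TN + FP)
    F1          = 2 P S / (P + S)

are reported as percentages. Overall accuracy is trace / total. 95%
confidence intervals use the Wald normal approximation on each metric's
natural denominator (sensitivity: the class's true count; specificity: the
negative count; precision: the predicted count; accuracy: the total).
Macro rows are unweighted means over the six classes with a normal CI from
the across-class sample standard deviation, mean +/- z * s / sqrt(C).
Reports round half-up to one decimal place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import CLASS_NAMES
from .exceptions import InvalidInputError

Z95 = 1.96


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (0.05 -> 0.1), not banker's rounding.

    A 1e-9 guard absorbs binary representation error (e.g. a mean stored as
    78.44999999999999 for exact 78.45 still rounds up to 78.5).
    """
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5 + 1e-9) / factor * (1 if x >= 0 else -1)


@dataclass
class ConfusionMatrix:
    """Counts[t][p] = number of samples of true class t predicted as p."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise InvalidInputError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise InvalidInputError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def one_vs_rest(self, class_i: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for class ``class_i`` against all others."""
        c = self.counts
        tp = int(c[class_i, class_i])
        fn = int(c[class_i].sum() - tp)
        fp = int(c[:, class_i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fp, tn, fn

    def to_csv(self, path) -> None:
        header = "," + ",".join(f"pred_{n}" for n in self.class_names)
        lines = [header] + [
            f"true_{n}," + ",".join(str(v) for v in row)
            for n, row in zip(self.class_names, self.counts)
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def confusion(y_true: Sequence[int], y_pred: Sequence[int],
              num_classes: int = len(CLASS_NAMES)) -> ConfusionMatrix:
    """Count the confusion matrix (rows = true class, columns = predicted)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise InvalidInputError("y_true and y_pred must be equal-length vectors")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= num_classes):
            raise InvalidInputError(f"{name} has labels outside 0..{num_classes - 1}")
    counts = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, CLASS_NAMES[:num_classes])


def proportion_ci(p: float, n: int, z: float = Z95) -> tuple[float, float]:
    """Wald 95% interval for a proportion, returned in percent.

    ``p +/- z * sqrt(p (1 - p) / n)`` clipped to [0, 100]. At p = 0 or 1 the
    interval degenerates to zero width at the boundary.
    """
    if not 0 <= p <= 1:
        raise InvalidInputError("p must be a proportion in [0, 1]")
    if n < 1:
        raise InvalidInputError("n must be at least 1")
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, (p - half)) * 100.0, min(1.0, (p + half)) * 100.0)


def macro_ci(values: Sequence[float], z: float = Z95
             ) -> tuple[float, Optional[tuple[float, float]]]:
    """Unweighted mean of per-class percentages with a normal 95% CI.

    The CI is ``mean +/- z * s / sqrt(C)`` with ``s`` the sample standard
    deviation (denominator C - 1) across the C class values. With fewer
    than two values the CI is undefined (None).
    """
    values = [v for v in values if v is not None]
    if not values:
        raise InvalidInputError("no defined class values to average")
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, None
    s = float(np.std(values, ddof=1))
    half = z * s / math.sqrt(len(values))
    return mean, (max(0.0, mean - half), min(100.0, mean + half))


@dataclass
class ClassMetrics:
    """One class's metrics in percent, each with its 95% CI (or None)."""

    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    f1: Optional[float]
    precision_ci: Optional[tuple[float, float]] = None
    sensitivity_ci: Optional[tuple[float, float]] = None
    specificity_ci: Optional[tuple[float, float]] = None
    f1_ci: Optional[tuple[float, float]] = None


def class_metrics(cm: ConfusionMatrix, class_i: int, z: float = Z95) -> ClassMetrics:
    """One-vs-rest metrics for one class with Wald CIs.

    A zero denominator yields None ("undefined", rendered as an em dash),
    never a silent 0. The F1 interval reuses the Wald machinery on the F1
    point value with the class's true count as n (delta method omitted).
    """
    if not 0 <= class_i < len(cm.class_names):
        raise InvalidInputError(f"class index {class_i} out of range")
    tp, fp, tn, fn = cm.one_vs_rest(class_i)

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    prec = ratio(tp, tp + fp)
    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    f1 = (2 * prec * sens / (prec + sens)
          if prec is not None and sens is not None and (prec + sens) > 0 else None)

    def ci(p: Optional[float], n: int) -> Optional[tuple[float, float]]:
        return proportion_ci(p, n) if p is not None and n > 0 else None

    return ClassMetrics(
        precision=None if prec is None else prec * 100,
        sensitivity=None if sens is None else sens * 100,
        specificity=None if spec is None else spec * 100,
        f1=None if f1 is None else f1 * 100,
        precision_ci=ci(prec, tp + fp),
        sensitivity_ci=ci(sens, tp + fn),
        specificity_ci=ci(spec, tn + fp),
        f1_ci=ci(f1, tp + fn),
    )


def overall_accuracy(cm: ConfusionMatrix, z: float = Z95
                     ) -> tuple[float, tuple[float, float]]:
    """Trace / total in percent with its Wald 95% CI."""
    if cm.total == 0:
        raise InvalidInputError("confusion matrix is empty")
    p = cm.trace / cm.total
    return p * 100.0, proportion_ci(p, cm.total, z)


@dataclass
class MetricsReport:
    """Per-class metrics, macro row, overall accuracy and the raw matrix."""

    confusion_matrix: ConfusionMatrix
    per_class: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)
    accuracy: float = 0.0
    accuracy_ci: tuple[float, float] = (0.0, 0.0)

    @staticmethod
    def _fmt(value, ci) -> str:
        if value is None:
            return "—"
        out = f"{round_half_up(value):.1f}"
        if ci is not None:
            out += f" ({round_half_up(ci[0]):.1f}–{round_half_up(ci[1]):.1f})"
        return out

    def to_markdown(self) -> str:
        rows = ["| Rhythm | Precision (%) | Sensitivity (%) | Specificity (%) "
                "| F1 (%) |",
                "|---|---|---|---|---|"]
        for name, m in self.per_class.items():
            rows.append(
                f"| {name} | {self._fmt(m.precision, m.precision_ci)} "
                f"| {self._fmt(m.sensitivity, m.sensitivity_ci)} "
                f"| {self._fmt(m.specificity, m.specificity_ci)} "
                f"| {self._fmt(m.f1, m.f1_ci)} |")
        mk = self.macro
        rows.append(
            f"| Mean | {self._fmt(*mk['precision'])} "
            f"| {self._fmt(*mk['sensitivity'])} "
            f"| {self._fmt(*mk['specificity'])} | {self._fmt(*mk['f1'])} |")
        rows.append(
            f"\nOverall accuracy: {self._fmt(self.accuracy, self.accuracy_ci)}%")
        return "\n".join(rows)

    def to_dict(self) -> dict:
        def pack(value, ci):
            return {"value": value, "ci": None if ci is None else list(ci)}

        return {
            "confusion_matrix": self.confusion_matrix.counts.tolist(),
            "per_class": {
                name: {
                    "precision": pack(m.precision, m.precision_ci),
                    "sensitivity": pack(m.sensitivity, m.sensitivity_ci),
                    "specificity": pack(m.specificity, m.specificity_ci),
                    "f1": pack(m.f1, m.f1_ci),
                } for name, m in self.per_class.items()
            },
            "macro": {k: pack(*v) for k, v in self.macro.items()},
            "accuracy": pack(self.accuracy, self.accuracy_ci),
        }


def evaluate(y_true: Sequence[int], y_pred: Sequence[int],
             num_classes: int = len(CLASS_NAMES)) -> MetricsReport:
    """Full metric suite from true and predicted labels."""
    cm = confusion(y_true, y_pred, num_classes)
    per_class = {cm.class_names[i]: class_metrics(cm, i)
                 for i in range(num_classes)}
    macro = {}
    for metric in ("precision", "sensitivity", "specificity", "f1"):
        values = [getattr(m, metric) for m in per_class.values()
                  if getattr(m, metric) is not None]
        # a metric can be undefined for every class (e.g. degenerate
        # predictions on a tiny split); the macro row is then undefined too
        macro[metric] = macro_ci(values) if values else (None, None)
    acc, acc_ci = overall_accuracy(cm)
    return MetricsReport(confusion_matrix=cm, per_class=per_class,
                         macro=macro, accuracy=acc, accuracy_ci=acc_ci)
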