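"""Multiclass confusion matrix and one-vs-rest per-class metrics.

For each class the C x C confusion matrix is collapsed to binary counts
(TP, FN, FP, TN) and scored by sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP) and F1 = 2TP/(2TP+FP+FN) — the harmonic
mean of precision and sensitivity.  ``reconstruct_counts`` inverts printed
sensitivity/precision back to integer counts, which lets published metric
tables be checked for internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "BinaryCounts",
    "ClassMetrics",
    "confusion_matrix",
    "binarize",
    "accuracy",
    "metrics_from_counts",
    "f1_from_rates",
    "reconstruct_counts",
    "metrics_table",
]

ConfusionMatrix = np.ndarray  # (C, C) ints: entry [g-1, p-1] = count given g, predicted p


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class rates; a rate is None when its denominator is zero."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None


def confusion_matrix(given: np.ndarray, predicted: np.ndarray, C: int) -> np.ndarray:
    """Counts with rows = given (true) label, columns = predicted label."""
    given = np.asarray(given, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if given.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {given.shape[0]} given vs {predicted.shape[0]} predicted"
        )
    for name, arr in (("given", given), ("predicted", predicted)):
        if arr.size and (arr.min() < 1 or arr.max() > C):
            raise ValueError(f"{name} labels outside [1, {C}]")
    cm = np.zeros((C, C), dtype=np.int64)
    np.add.at(cm, (given - 1, predicted - 1), 1)
    return cm


def binarize(cm: np.ndarray, c: int) -> BinaryCounts:
    """One-vs-rest counts for 1-based class c."""
    C = cm.shape[0]
    if not 1 <= c <= C:
        raise ValueError(f"class {c} outside [1, {C}]")
    i = c - 1
    tp = int(cm[i, i])
    fn = int(cm[i, :].sum() - cm[i, i])
    fp = int(cm[:, i].sum() - cm[i, i])
    tn = int(cm.sum() - tp - fn - fp)
    return BinaryCounts(tp, fn, fp, tn)


def accuracy(nr: int, Nt: int) -> float:
    """Overall prediction accuracy: correct / evaluated."""
    if Nt <= 0:
        raise ValueError("Nt must be positive")
    if not 0 <= nr <= Nt:
        raise ValueError(f"nr={nr} outside [0, {Nt}]")
    return nr / Nt


def _rate(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics_from_counts(b: BinaryCounts) -> ClassMetrics:
    """Sensitivity, specificity, precision and F1 from binary counts.

    Undefined rates (zero denominator) come back as None rather than 0."""
    return ClassMetrics(
        accuracy=_rate(b.tp + b.tn, b.total),
        sensitivity=_rate(b.tp, b.tp + b.fn),
        specificity=_rate(b.tn, b.tn + b.fp),
        precision=_rate(b.tp, b.tp + b.fp),
        f1=_rate(2 * b.tp, 2 * b.tp + b.fp + b.fn),
    )


def f1_from_rates(precision: float, sensitivity: float) -> float | None:
    """Harmonic mean of precision and sensitivity; None if both are zero."""
    if precision < 0 or sensitivity < 0:
        raise ValueError("rates must be nonnegative")
    if precision + sensitivity == 0:
        return None
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def reconstruct_counts(
    n_class: int, n_total: int, sensitivity: float, precision: float
) -> BinaryCounts:
    """Invert printed sensitivity/precision to integer one-vs-rest counts.

    Given the class size and the evaluated total, TP = round(sens * n_class)
    and FP = round(TP / precision) - TP (round half up).  Raises if the
    implied counts are inconsistent (negative).
    """
    if not 0 < n_class < n_total:
        raise ValueError("need 0 < n_class < n_total")
    if not (0 < sensitivity <= 1 and 0 < precision <= 1):
        raise ValueError("rates must be in (0, 1]")
    tp = _round_half_up(sensitivity * n_class)
    fn = n_class - tp
    fp = _round_half_up(tp / precision) - tp
    tn = (n_total - n_class) - fp
    if min(tp, fn, fp, tn) < 0:
        raise ValueError(
            f"inconsistent rates: reconstructed counts ({tp}, {fn}, {fp}, {tn})"
        )
    return BinaryCounts(tp, fn, fp, tn)


def metrics_table(
    given: np.ndarray,
    predicted: np.ndarray,
    C: int,
    class_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-class metric table (one row per class, plus counts)."""
    cm = confusion_matrix(given, predicted, C)
    names = class_names if class_names is not None else [
        f"class_{i}" for i in range(1, C + 1)
    ]
    rows = []
    for c in range(1, C + 1):
        b = binarize(cm, c)
        m = metrics_from_counts(b)
        rows.append(
            {
                "class": names[c - 1],
                "n_samples": b.tp + b.fn,
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "precision": m.precision,
                "f1": m.f1,
                "tp": b.tp,
                "fn": b.fn,
                "fp": b.fp,
                "tn": b.tn,
            }
        )
    return pd.DataFrame(rows)
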