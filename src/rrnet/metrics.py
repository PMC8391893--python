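"""Confusion-matrix algebra, per-class ACC/SEN/SPE, and ROC averaging.

Matrices are stored as true-class x predicted-class counts in the canonical
order (AFIB, AFL, NSR). The per-class tallies follow the convention

* TP = the class's diagonal entry,
* FN = off-diagonal of the class's *true* row,
* FP = off-diagonal of the class's *predicted* column,
* TN = sum of the other diagonal entries (the "other classes classified as
  themselves" convention); the standard multiclass TN
  (total - row - column + diagonal) is reported alongside. The two coincide
  whenever confusions between the other classes are zero.

Percentages are rounded half-away-from-zero to two decimals, matching how
such tables are conventionally printed. Undefined metrics (zero
denominators) propagate as ``nan``, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .synthetic import CLASSES

__all__ = ["ConfusionMatrix", "ClassMetrics", "ROCResult", "confusion",
           "pool", "class_metrics", "metrics_table", "collapse_binary",
           "binary_metrics", "roc", "round2"]

BINARY_CLASSES = ("Arrhythmia", "Non-Arrhythmia")


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (printed-table convention)."""
    if np.isnan(x):
        return float("nan")
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True, eq=False)
class ConfusionMatrix:
    """True-class x predicted-class integer counts with a fixed class order."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassMetrics:
    """One class's tally and percent metrics (two printed decimals)."""

    cls: str
    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    SEN: float
    SPE: float
    TN_standard: int = 0


def confusion(true_labels, pred_labels,
              classes: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=object)
    pred_labels = np.asarray(pred_labels, dtype=object)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label arrays must have equal length")
    lut = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        if t not in lut or p not in lut:
            raise ValueError(f"unknown label: {t!r} / {p!r}")
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts, classes)


def pool(matrices) -> ConfusionMatrix:
    """Elementwise sum of per-fold matrices (same class order required)."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("nothing to pool")
    classes = matrices[0].classes
    for m in matrices[1:]:
        if m.classes != classes:
            raise ValueError("class order mismatch")
    return ConfusionMatrix(sum(m.counts for m in matrices), classes)


def _pct(num: float, den: float) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def class_metrics(cm: ConfusionMatrix, cls: str) -> ClassMetrics:
    """ACC/SEN/SPE for one class (percent, rounded to two decimals)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    i = cm.classes.index(cls)
    c = cm.counts
    TP = int(c[i, i])
    FN = int(c[i, :].sum() - TP)
    FP = int(c[:, i].sum() - TP)
    TN = int(np.trace(c) - TP)
    TN_std = int(c.sum() - c[i, :].sum() - c[:, i].sum() + TP)
    acc = _pct(TP + TN, TP + TN + FP + FN)
    sen = _pct(TP, TP + FN)
    spe = _pct(TN, TN + FP)
    return ClassMetrics(cls, TP, TN, FP, FN,
                        round2(acc), round2(sen), round2(spe),
                        TN_standard=TN_std)


def metrics_table(cm: ConfusionMatrix) -> dict[str, ClassMetrics]:
    return {cls: class_metrics(cm, cls) for cls in cm.classes}


def collapse_binary(cm3: ConfusionMatrix) -> ConfusionMatrix:
    """Merge AFIB+AFL into an arrhythmia class; NSR is non-arrhythmia."""
    if cm3.classes != CLASSES:
        raise ValueError("expected canonical (AFIB, AFL, NSR) order")
    c = cm3.counts
    arr = [0, 1]
    nsr = [2]
    out = np.array([
        [c[np.ix_(arr, arr)].sum(), c[np.ix_(arr, nsr)].sum()],
        [c[np.ix_(nsr, arr)].sum(), c[np.ix_(nsr, nsr)].sum()],
    ])
    return ConfusionMatrix(out, BINARY_CLASSES)


def binary_metrics(cm2: ConfusionMatrix) -> dict[str, float]:
    """Arrhythmia-vs-non-arrhythmia metrics, both label orientations.

    ``sensitivity_arrhythmia`` is true arrhythmia correctly flagged /
    all true arrhythmia (the Abstract-style orientation);
    ``specificity_arrhythmia`` is true non-arrhythmia correctly passed /
    all true non-arrhythmia. The swapped presentation (sensitivity and
    specificity exchanged) is also emitted under explicit ``swapped_*``
    keys since both conventions appear in print.
    """
    if cm2.counts.shape != (2, 2) or cm2.total == 0:
        raise ValueError("need a non-empty 2x2 matrix")
    m = class_metrics(cm2, cm2.classes[0])
    return {
        "ACC": m.ACC,
        "sensitivity_arrhythmia": m.SEN,
        "specificity_arrhythmia": m.SPE,
        "swapped_SEN": m.SPE,
        "swapped_SPE": m.SEN,
    }


@dataclass(frozen=True)
class ROCResult:
    """One-vs-rest ROC curves with micro and macro averages."""

    per_class: dict[str, tuple[np.ndarray, np.ndarray, float]]  # fpr, tpr, auc
    micro: tuple[np.ndarray, np.ndarray, float]
    macro: tuple[np.ndarray, np.ndarray, float]
    absent_classes: tuple[str, ...] = ()


def roc(scores: np.ndarray, true_labels,
        classes: tuple[str, ...] = CLASSES,
        macro_grid_points: int = 1001) -> ROCResult:
    """One-vs-rest ROC per class plus micro/macro averages.

    The micro average pools all (score, indicator) pairs; the macro average
    interpolates each class's TPR onto a common FPR grid and averages.
    Classes absent from the truth get no curve and are flagged.
    """
    scores = np.asarray(scores, dtype=float)
    true_labels = np.asarray(true_labels, dtype=object)
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("scores must be (n, n_classes)")
    lut = {c: i for i, c in enumerate(classes)}
    y = np.asarray([lut[t] for t in true_labels])
    onehot = np.eye(len(classes))[y]

    per_class: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}
    absent = []
    for i, cls in enumerate(classes):
        if onehot[:, i].sum() in (0, len(y)):
            absent.append(cls)
            continue
        fpr, tpr, _ = _sk_roc_curve(onehot[:, i], scores[:, i])
        per_class[cls] = (fpr, tpr, float(_sk_auc(fpr, tpr)))

    fpr_mi, tpr_mi, _ = _sk_roc_curve(onehot.ravel(), scores.ravel())
    micro = (fpr_mi, tpr_mi, float(_sk_auc(fpr_mi, tpr_mi)))

    grid = np.linspace(0.0, 1.0, macro_grid_points)
    mean_tpr = np.zeros_like(grid)
    for fpr, tpr, _ in per_class.values():
        mean_tpr += np.interp(grid, fpr, tpr)
    if per_class:
        mean_tpr /= len(per_class)
    macro = (grid, mean_tpr, float(_sk_auc(grid, mean_tpr)))
    return ROCResult(per_class, micro, macro, tuple(absent))
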