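"""Classification and segmentation evaluation metrics.

Per-class metrics are one-vs-rest (each class gets its own accuracy,
specificity, precision, recall and F1). Ratios with a zero denominator
are reported as NaN — explicitly undefined, never silently 0. The Dice
coefficient of two empty masks is defined as 1.0 (perfect agreement on
absence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MeanDice",
    "confusion_matrix",
    "per_class_metrics",
    "f1_from_pr",
    "dice_coefficient",
    "mean_dice",
    "round_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square contingency table; rows are truth, columns are prediction."""

    class_set: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_set", tuple(self.class_set))
        m = np.asarray(self.counts)
        if m.shape != (len(self.class_set), len(self.class_set)):
            raise ValueError("counts shape must match class_set")
        if np.any(m < 0) or not np.issubdtype(m.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", m)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, cls) -> int:
        try:
            return self.class_set.index(cls)
        except ValueError:
            raise ValueError(f"class {cls!r} not in class_set {self.class_set}") from None


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class; NaN marks an undefined ratio."""

    accuracy: float
    specificity: float
    precision: float
    recall: float
    f1: float


def confusion_matrix(truth: Sequence, pred: Sequence, class_set: Sequence) -> ConfusionMatrix:
    """Tally a truth-by-prediction contingency table over *class_set*."""
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(pred)} predictions")
    class_set = tuple(class_set)
    index = {c: i for i, c in enumerate(class_set)}
    counts = np.zeros((len(class_set), len(class_set)), dtype=np.int64)
    for t, p in zip(truth, pred):
        if t not in index:
            raise ValueError(f"unknown truth label {t!r}; not in class_set {class_set}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}; not in class_set {class_set}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(class_set, counts)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def per_class_metrics(cm: ConfusionMatrix, cls) -> ClassMetrics:
    """One-vs-rest accuracy / specificity / precision / recall / F1 of *cls*."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    i = cm.index(cls)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = f1_from_pr(precision, recall)
    return ClassMetrics(
        accuracy=_ratio(tp + tn, cm.total),
        specificity=_ratio(tn, tn + fp),
        precision=precision,
        recall=recall,
        f1=f1,
    )


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R) of a precision/recall pair."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0:
        raise ValueError("F1 undefined when precision + recall == 0")
    return 2.0 * precision * recall / (precision + recall)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks.

    Both-empty is defined as 1.0.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / size


@dataclass(frozen=True)
class MeanDice:
    """Mean Dice over mask pairs.

    ``overall`` weights every pair equally (so groups enter by their pair
    counts); ``macro`` is the unweighted mean of the per-group means and
    is None when no groups were given.
    """

    overall: float
    per_group: Mapping
    macro: Optional[float]
    per_pair: tuple


def mean_dice(pairs: Sequence[tuple], group_labels: Optional[Sequence] = None) -> MeanDice:
    """Arithmetic mean of per-pair Dice, overall and per group."""
    if len(pairs) == 0:
        raise ValueError("mean_dice requires at least one mask pair")
    if group_labels is not None and len(group_labels) != len(pairs):
        raise ValueError("group_labels must match pairs in length")
    dices = [dice_coefficient(a, b) for a, b in pairs]
    per_group: dict = {}
    macro = None
    if group_labels is not None:
        for g, d in zip(group_labels, dices):
            per_group.setdefault(g, []).append(d)
        per_group = {g: float(np.mean(v)) for g, v in per_group.items()}
        macro = float(np.mean(list(per_group.values())))
    return MeanDice(
        overall=float(np.mean(dices)),
        per_group=per_group,
        macro=macro,
        per_pair=tuple(dices),
    )


def round_report(x: float, ndigits: int = 3) -> float:
    """Report rounding: *ndigits* decimals, round-half-to-even."""
    if math.isnan(x):
        return x
    return float(round(x, ndigits))
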