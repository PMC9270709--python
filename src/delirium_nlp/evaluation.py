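"""Metrics for the 3-class sentence classifiers.

Covers the train/validation/test split, micro and macro F1,
row/column-normalized confusion matrices, one-vs-rest ROC/AUC, seeded
percentile-bootstrap confidence intervals, and per-category pairwise
interrater agreement.  The fixed class order (POSITIVE, NEGATIVE,
NEITHER) is used for every matrix and vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import (confusion_matrix as _sk_confusion,
                             precision_recall_fscore_support, roc_curve)

from .labels import CLASS_ORDER, Label, as_label

__all__ = [
    "ConfusionMatrix", "MetricWithCI", "F1Report",
    "split_dataset", "f1_scores", "confusion", "normalize",
    "roc_auc_ovr", "bootstrap_ci", "pairwise_ira",
]


def _as_indices(labels: Sequence) -> np.ndarray:
    order = {lab: i for i, lab in enumerate(CLASS_ORDER)}
    return np.array([order[as_label(l)] for l in labels])


# ---------------------------------------------------------------------------
# data split

def split_dataset(
    n: int, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded disjoint, exhaustive (train, val, test) index split.

    Validation and test take ``round(f * n)`` items each; train gets the
    remainder, so e.g. ``n=200471`` with the default 60/20/20 fractions
    yields sizes (120283, 40094, 40094).
    """
    if n < 3:
        raise ValueError("need n >= 3 to form three non-trivial parts")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    if n_val + n_test >= n:
        raise ValueError("validation and test fractions leave no training data")
    perm = np.random.default_rng(seed).permutation(n)
    train = perm[: n - n_val - n_test]
    val = perm[n - n_val - n_test: n - n_test]
    test = perm[n - n_test:]
    return train, val, test


# ---------------------------------------------------------------------------
# F1

@dataclass(frozen=True)
class F1Report:
    micro_f1: float
    macro_f1: float
    precision: np.ndarray  # per class, fixed order
    recall: np.ndarray
    f1: np.ndarray


def f1_scores(truth: Sequence, predicted: Sequence) -> F1Report:
    """Micro/macro F1 and per-class precision/recall/F1.

    Per-class scores are one-vs-rest with the 0-when-undefined
    convention; macro F1 is the unweighted mean over the three classes
    (minority classes count fully); micro F1 pools one-vs-rest counts
    globally and, for single-label multiclass data, equals accuracy.
    """
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    y, p = _as_indices(truth), _as_indices(predicted)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, p, labels=[0, 1, 2], zero_division=0)
    # micro: pool one-vs-rest counts globally, then TP / (TP + (FP+FN)/2)
    tp = fp = fn = 0
    for c in range(3):
        tp += int(((y == c) & (p == c)).sum())
        fp += int(((y != c) & (p == c)).sum())
        fn += int(((y == c) & (p != c)).sum())
    micro = tp / (tp + 0.5 * (fp + fn)) if tp + fp + fn else 0.0
    return F1Report(micro_f1=micro, macro_f1=float(f1.mean()),
                    precision=prec, recall=rec, f1=f1)


# ---------------------------------------------------------------------------
# confusion matrices

@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a nonnegative 3x3 matrix")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(truth: Sequence, predicted: Sequence) -> ConfusionMatrix:
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    y, p = _as_indices(truth), _as_indices(predicted)
    return ConfusionMatrix(_sk_confusion(y, p, labels=[0, 1, 2]))


def normalize(matrix: ConfusionMatrix, axis: str) -> np.ndarray:
    """Row-normalize (diagonal = recall) or column-normalize (= precision).

    A zero row/column stays all-zero rather than dividing by zero.
    """
    counts = matrix.counts.astype(float)
    if axis == "row":
        totals = counts.sum(axis=1, keepdims=True)
    elif axis == "column":
        totals = counts.sum(axis=0, keepdims=True)
    else:
        raise ValueError("axis must be 'row' or 'column'")
    return np.divide(counts, totals, out=np.zeros_like(counts),
                     where=totals > 0)


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc_ovr(
    truth: Sequence, scores: np.ndarray, positive_class: Label | str,
) -> tuple[np.ndarray, float]:
    """One-vs-rest ROC points and trapezoidal AUC for one class.

    ``scores`` is (n, 3) on the simplex in fixed class order.  The AUC
    equals the Mann-Whitney U statistic normalized by n+ * n-.  Raises
    when the class is absent from (or universal in) the truth vector.
    """
    positive_class = as_label(positive_class)
    y = _as_indices(truth)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape != (len(y), 3):
        raise ValueError("scores must be (n, 3)")
    if scores.min() < -1e-9 or np.abs(scores.sum(axis=1) - 1).max() > 1e-6:
        raise ValueError("scores rows must lie on the simplex")
    c = {lab: i for i, lab in enumerate(CLASS_ORDER)}[positive_class]
    binary = (y == c).astype(int)
    if binary.min() == binary.max():
        raise ValueError(
            f"AUC undefined: class {positive_class.value} is "
            f"{'absent from' if binary.max() == 0 else 'universal in'} truth")
    fpr, tpr, _ = roc_curve(binary, scores[:, c])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# bootstrap

@dataclass(frozen=True)
class MetricWithCI:
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def bootstrap_ci(
    metric_fn: Callable[..., float], data: tuple[np.ndarray, ...] | np.ndarray,
    n_boot: int = 1000, seed: int = 0,
) -> MetricWithCI:
    """Percentile 95% bootstrap CI, resampling evaluation rows jointly.

    ``data`` is one array or a tuple of equal-length arrays passed to
    ``metric_fn``; rows are the resampling unit.  Errors out when the
    metric is undefined (raises or returns non-finite) on more than 10%
    of resamples.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arrays = (np.asarray(data),) if not isinstance(data, tuple) \
        else tuple(np.asarray(a) for a in data)
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all data arrays must share their first dimension")
    point = float(metric_fn(*arrays))
    rng = np.random.default_rng(seed)
    stats: list[float] = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            v = float(metric_fn(*(a[idx] for a in arrays)))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            v = np.nan
        if np.isfinite(v):
            stats.append(v)
        else:
            failures += 1
    if failures > 0.1 * n_boot:
        raise ValueError(
            f"metric undefined on {failures}/{n_boot} bootstrap resamples")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return MetricWithCI(point=point, ci_low=float(min(lo, point)),
                        ci_high=float(max(hi, point)), n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# interrater agreement

def pairwise_ira(labels_a: Sequence, labels_b: Sequence) -> dict[Label, float]:
    """Per-category positive specific agreement between two raters.

    For category c: ``2 * |a==c and b==c| / (|a==c| + |b==c|)`` — the
    between-rater F1 for that category.  Categories used by neither
    rater are omitted from the result.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    a = _as_indices(labels_a)
    b = _as_indices(labels_b)
    out: dict[Label, float] = {}
    for i, lab in enumerate(CLASS_ORDER):
        na, nb = int((a == i).sum()), int((b == i).sum())
        if na + nb == 0:
            continue  # category unused by both raters: agreement undefined
        both = int(((a == i) & (b == i)).sum())
        out[lab] = 2.0 * both / (na + nb)
    return out
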