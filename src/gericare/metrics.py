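"""Multiclass evaluation: confusion matrix, OvR precision/recall/F1, macro
and weighted F1, and one-vs-rest ROC AUC.

Conventions: confusion-matrix rows are actual classes and columns are
predicted classes, so the diagonal counts correct predictions.  Per-class
scores use the one-against-rest reduction:

    precision_i = diag_i / column_sum_i
    recall_i    = diag_i / row_sum_i
    F1_i        = 2 P R / (P + R)

Macro F1 is the unweighted mean of the per-class F1s; weighted F1 is
sum_i (k_i / N) F1_i with k_i the actual count of class i.  (The weights
already sum to one, so no further division by the class count is applied.)
Empty denominators produce 0 with a flag rather than NaN.

AUC is the area under the one-vs-rest ROC computed by the trapezoidal rule,
with ties handled by midranks (equivalently, the Mann-Whitney statistic).
Everything is computed at full precision; ``round4`` applies the half-up
4-decimal rounding used for reported tables.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "precision_recall_f1",
    "f1_score",
    "macro_f1",
    "weighted_f1",
    "roc_auc_ovr",
    "round4",
]


def round4(x: float) -> float:
    """Round half-up to 4 decimals (report-time rounding only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (c, c) ints; rows actual, columns predicted
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if counts.shape != (c, c) or (counts < 0).any():
            raise ValueError("confusion counts must be a nonnegative c x c matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def n_errors(self) -> int:
        return self.total - self.n_correct

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def accuracy(self) -> float:
        return self.n_correct / self.total if self.total else 0.0

    def per_class_accuracy(self) -> dict[str, float]:
        """Recall of each class (diagonal over actual count)."""
        rows = self.row_sums()
        return {
            cls: (self.counts[i, i] / rows[i] if rows[i] else 0.0)
            for i, cls in enumerate(self.classes)
        }


def confusion(
    actual: Sequence[str],
    predicted: Sequence[str],
    classes: Optional[Sequence[str]] = None,
) -> ConfusionMatrix:
    """Exact label-pair counting; unknown labels raise by name."""
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    if classes is None:
        classes = sorted(set(actual) | set(predicted))
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in index:
            raise ValueError(f"unknown actual label {a!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclasses.dataclass(frozen=True)
class ClassScores:
    precision: float
    recall: float
    f1: float
    undefined_precision: bool = False
    undefined_recall: bool = False


def precision_recall_f1(cm: ConfusionMatrix) -> dict[str, ClassScores]:
    """Per-class OvR precision/recall/F1 from a confusion matrix."""
    rows, cols = cm.row_sums(), cm.col_sums()
    out: dict[str, ClassScores] = {}
    for i, cls in enumerate(cm.classes):
        tp = cm.counts[i, i]
        undef_p = cols[i] == 0
        undef_r = rows[i] == 0
        p = 0.0 if undef_p else tp / cols[i]
        r = 0.0 if undef_r else tp / rows[i]
        out[cls] = ClassScores(float(p), float(r), f1_score(p, r), bool(undef_p), bool(undef_r))
    return out


def macro_f1(per_class_f1: Sequence[float]) -> float:
    """Unweighted mean of per-class F1 values."""
    f1 = np.asarray(per_class_f1, dtype=float)
    if f1.size == 0:
        raise ValueError("macro F1 of an empty vector is undefined")
    return float(f1.mean())


def weighted_f1(per_class_f1: Sequence[float], class_counts: Sequence[int], n: int) -> float:
    """Sum of (k_i / N) * F1_i; class counts must sum to N."""
    f1 = np.asarray(per_class_f1, dtype=float)
    k = np.asarray(class_counts, dtype=float)
    if f1.shape != k.shape:
        raise ValueError("per-class F1 and class counts length mismatch")
    if k.sum() != n:
        raise ValueError(f"class counts sum to {k.sum()}, expected N={n}")
    return float(np.sum((k / n) * f1))


def roc_auc_ovr(
    actual: Sequence[str],
    scores: dict[str, Sequence[float]],
) -> dict[str, Optional[float]]:
    """Per-class one-vs-rest ROC AUC with midrank tie handling.

    ``scores[c][i]`` is the classifier's score for sample i belonging to
    class c.  A class with no positive or no negative samples gets None
    (AUC undefined).
    """
    actual = list(actual)
    out: dict[str, Optional[float]] = {}
    for cls, s in scores.items():
        s = np.asarray(s, dtype=float)
        if len(s) != len(actual):
            raise ValueError(f"scores for class {cls!r} have wrong length")
        if not np.isfinite(s).all():
            raise ValueError(f"non-finite score for class {cls!r}")
        pos = np.array([a == cls for a in actual])
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[cls] = None
            continue
        ranks = rankdata(s)  # midranks for ties
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        out[cls] = float(auc)
    return out
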