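"""Fold accuracies, confusion matrices and derived classification metrics.

Accuracies are reported rounded half-up to three decimals, matching the
convention of clinical deep-learning reports, while full precision is kept
internally. Precision with an empty predicted column is reported as NaN
with a warning rather than silently coerced to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal half-up rounding (0.8745 -> 0.875), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fold_accuracy(total: int, correct: int) -> float:
    """correct / total for one fold and category."""
    if total <= 0:
        raise ZeroDivisionError("accuracy undefined for zero total patches")
    if not 0 <= correct <= total:
        raise ValueError(f"correct={correct} outside [0, {total}]")
    return correct / total


def average_folds(accuracies: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-fold accuracies."""
    if len(accuracies) == 0:
        raise ValueError("cannot average an empty list of fold accuracies")
    return float(np.mean(accuracies))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are ground truth, columns are predictions."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if counts.shape != (k, k):
            raise ValueError(f"counts shape {counts.shape} does not match {k} classes")
        if (counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def confusion(
    truth: Sequence, predicted: Sequence, classes: Sequence
) -> ConfusionMatrix:
    """Tally counts[i][j] = #(truth = classes[i] and predicted = classes[j])."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted differ in length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise ValueError(f"label pair ({t!r}, {p!r}) outside classes {classes}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=tuple(str(c) for c in classes))


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class recall/precision/F1 plus overall accuracy of a matrix."""

    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    overall_accuracy: float
    class_names: tuple[str, ...]


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """recall_i = cm[i,i]/rowsum_i; precision_i = cm[i,i]/colsum_i;
    F1 the harmonic mean; overall accuracy = trace / grand total.

    Empty rows or columns yield NaN for the affected metric (with a warning
    for precision) instead of a silently inflating zero.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm.counts).astype(float)
    rows = cm.row_totals().astype(float)
    cols = cm.col_totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(rows > 0, diag / rows, np.nan)
        precision = np.where(cols > 0, diag / cols, np.nan)
        f1 = 2 * precision * recall / (precision + recall)
        f1 = np.where((precision + recall) > 0, f1, np.nan)
    for i, c in enumerate(cols):
        if c == 0:
            warnings.warn(
                f"class {cm.class_names[i]!r} never predicted; precision undefined",
                stacklevel=2,
            )
    return ClassMetrics(
        recall=recall,
        precision=precision,
        f1=f1,
        overall_accuracy=float(diag.sum() / cm.total),
        class_names=cm.class_names,
    )


@dataclass
class FoldReport:
    """Per-category fold accuracies plus the image-level confusion matrix.

    ``per_category`` maps a category name to a list of (total, correct,
    accuracy) triplets, one per fold; ``averaged`` holds the unweighted mean
    of the fold accuracies per category.
    """

    per_category: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    image_level: Optional[ConfusionMatrix] = None

    @property
    def averaged(self) -> dict[str, float]:
        return {
            name: average_folds([a for _, _, a in triplets])
            for name, triplets in self.per_category.items()
            if triplets
        }

    def to_dict(self) -> dict:
        out: dict = {
            "per_category": {
                name: [
                    {
                        "total": t,
                        "correct": c,
                        "accuracy": a,
                        "accuracy_rounded": round_half_up(a),
                    }
                    for t, c, a in triplets
                ]
                for name, triplets in self.per_category.items()
            },
            "averaged_accuracy": {
                name: round_half_up(v) for name, v in self.averaged.items()
            },
        }
        if self.image_level is not None:
            m = class_metrics(self.image_level)
            out["image_level"] = {
                "classes": list(self.image_level.class_names),
                "counts": self.image_level.counts.tolist(),
                "recall": [_json_num(v) for v in m.recall],
                "precision": [_json_num(v) for v in m.precision],
                "f1": [_json_num(v) for v in m.f1],
                "overall_accuracy": m.overall_accuracy,
                "overall_accuracy_rounded": round_half_up(m.overall_accuracy),
            }
        return out

    def render(self) -> str:
        """Plain-text tables: per-category fold accuracies, then the matrix."""
        lines = ["Patch-level fold validation accuracy"]
        header = ["Category"]
        n_folds = max((len(v) for v in self.per_category.values()), default=0)
        for i in range(n_folds):
            header += [f"Fold{i + 1} total", "correct", "acc"]
        header.append("Averaged")
        lines.append("\t".join(header))
        for name, triplets in self.per_category.items():
            row = [name]
            for t, c, a in triplets:
                row += [str(t), str(c), f"{round_half_up(a):.3f}"]
            row.append(f"{round_half_up(self.averaged[name]):.3f}")
            lines.append("\t".join(row))
        if self.image_level is not None:
            m = class_metrics(self.image_level)
            lines.append("")
            lines.append("Image-level confusion matrix (rows truth, cols predicted)")
            lines.append("\t".join(["truth\\pred", *self.image_level.class_names,
                                    "total", "recall"]))
            for i, name in enumerate(self.image_level.class_names):
                row = [name, *map(str, self.image_level.counts[i])]
                row.append(str(int(self.image_level.row_totals()[i])))
                r = m.recall[i]
                row.append("-" if np.isnan(r) else f"{round_half_up(r):.3f}")
                lines.append("\t".join(row))
            lines.append(
                f"Overall accuracy: {round_half_up(m.overall_accuracy):.3f}"
            )
        return "\n".join(lines)


def _json_num(v: float):
    return None if np.isnan(v) else float(v)
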