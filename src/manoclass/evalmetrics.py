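"""Evaluation suite: confusion matrix, accuracy, precision/recall/F1 reports.

Conventions used throughout:

* one-vs-rest precision and recall, with the 0-by-convention rule when a
  denominator vanishes;
* F1 is the harmonic mean of precision and recall;
* printed percentages are truncated (not rounded) to two decimals — 31/32
  prints as ``96.87`` — while full precision is kept internally;
* macro averages are the headline multi-class summary; micro averages and
  per-class values are always included (for single-label problems the micro
  F1 equals the accuracy).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion_matrix",
    "accuracy",
    "precision_recall",
    "f1",
    "classification_report",
    "truncate_pct",
    "format_pct",
]


def truncate_pct(fraction: float, decimals: int = 2) -> float:
    """Express a fraction as a percentage truncated to ``decimals`` places."""
    scale = 10 ** decimals
    return math.floor(fraction * 100 * scale + 1e-9) / scale


def format_pct(fraction: float, decimals: int = 2) -> str:
    return f"{truncate_pct(fraction, decimals):.{decimals}f}"


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K count matrix; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_order: tuple[Hashable, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ValueError(f"counts shape {counts.shape} != ({k}, {k})")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, label: Hashable) -> int:
        try:
            return self.class_order.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in class order") from None

    def support(self, label: Hashable) -> int:
        return int(self.counts[self.index(label)].sum())


def confusion_matrix(
    true_labels: Sequence[Hashable],
    predicted_labels: Sequence[Hashable],
    class_order: Sequence[Hashable],
) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a matrix ordered by ``class_order``."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    order = tuple(class_order)
    known = set(order)
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}")
    if not true_labels:
        counts = np.zeros((len(order), len(order)), dtype=np.int64)
        return ConfusionMatrix(counts, order)
    # map to indices so labels may be enums or arbitrary hashables
    lut = {lab: i for i, lab in enumerate(order)}
    y_true = [lut[t] for t in true_labels]
    y_pred = [lut[p] for p in predicted_labels]
    counts = _sk_confusion_matrix(y_true, y_pred, labels=range(len(order)))
    return ConfusionMatrix(counts.astype(np.int64), order)


def accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: the fraction of correctly classified items."""
    if cm.total == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def precision_recall(cm: ConfusionMatrix, positive_class: Hashable) -> tuple[float, float]:
    """One-vs-rest precision and recall for ``positive_class``.

    Either value is 0 by convention when its denominator is 0.
    """
    i = cm.index(positive_class)
    tp = float(cm.counts[i, i])
    fp = float(cm.counts[:, i].sum() - cm.counts[i, i])
    fn = float(cm.counts[i, :].sum() - cm.counts[i, i])
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MetricReport:
    """Per-class and averaged metrics for one classification task."""

    class_order: tuple[Hashable, ...]
    per_class: Mapping[Hashable, dict]
    accuracy: float
    macro: dict
    micro: dict
    total: int

    def to_dict(self) -> dict:
        def name(lab: Hashable) -> str:
            return getattr(lab, "value", None) or str(lab)

        return {
            "accuracy_pct": truncate_pct(self.accuracy),
            "macro": {k: truncate_pct(v) for k, v in self.macro.items()},
            "micro": {k: truncate_pct(v) for k, v in self.micro.items()},
            "per_class": {
                name(lab): {
                    "precision_pct": truncate_pct(m["precision"]),
                    "recall_pct": truncate_pct(m["recall"]),
                    "f1_pct": truncate_pct(m["f1"]),
                    "support": m["support"],
                }
                for lab, m in self.per_class.items()
            },
            "total": self.total,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def classification_report(cm: ConfusionMatrix) -> MetricReport:
    """Full one-vs-rest report from a confusion matrix."""
    per_class: dict[Hashable, dict] = {}
    for lab in cm.class_order:
        p, r = precision_recall(cm, lab)
        per_class[lab] = {
            "precision": p,
            "recall": r,
            "f1": f1(p, r),
            "support": cm.support(lab),
        }
    k = len(cm.class_order)
    macro = {
        "precision": sum(m["precision"] for m in per_class.values()) / k,
        "recall": sum(m["recall"] for m in per_class.values()) / k,
        "f1": sum(m["f1"] for m in per_class.values()) / k,
    }
    tp = float(np.trace(cm.counts))
    fp = float(cm.total - np.trace(cm.counts))  # every error is one FP and one FN
    micro_p = tp / (tp + fp) if tp + fp > 0 else 0.0
    micro = {"precision": micro_p, "recall": micro_p, "f1": micro_p}
    return MetricReport(
        class_order=cm.class_order,
        per_class=per_class,
        accuracy=accuracy(cm),
        macro=macro,
        micro=micro,
        total=cm.total,
    )


def plot_confusion(cm: ConfusionMatrix, path, title: str = "Confusion matrix") -> None:
    """Optional heatmap writer (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.counts, cmap="Blues")
    names = [getattr(lab, "value", None) or str(lab) for lab in cm.class_order]
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    for i in range(len(names)):
        for j in range(len(names)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center", fontsize=8)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
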