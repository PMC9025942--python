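"""One-vs-rest confusion counts and the derived classification metrics.

For each rhythm class c, the 3-class predictions are collapsed to a binary
problem (c vs rest) giving TP/TN/FP/FN, from which six metrics follow:

    accuracy    = (TP + TN) / n
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    f_measure   = 2 P R / (P + R)
    sensitivity = TP / (TP + FN)   (identical to recall)
    specificity = TN / (TN + FP)

Zero-denominator ratios are reported as NaN with a warning — silently
substituting 0 or 1 would corrupt macro averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .records import CLASSES

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "confusion_matrix_3x3",
    "compute_metrics",
    "macro_average",
    "render_confusion_figure",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f_measure",
                "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    class_label: str
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    n_eval: int
    counts: list[ConfusionCounts] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro": self.macro,
            "n_eval": self.n_eval,
            "counts": [
                {"class": c.class_label, "TP": c.TP, "TN": c.TN,
                 "FP": c.FP, "FN": c.FN}
                for c in self.counts
            ],
        }


def confusion_counts(true_labels, predicted_labels) -> list[ConfusionCounts]:
    """Per-class one-vs-rest TP/TN/FP/FN; each class's counts sum to n."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"{len(true_labels)} true vs {len(predicted_labels)} predicted labels"
        )
    for l in set(true_labels) | set(predicted_labels):
        if l not in CLASSES:
            raise ValueError(f"unknown label {l!r}")
    n = len(true_labels)
    out = []
    for cls in CLASSES:
        tp = sum(1 for t, p in zip(true_labels, predicted_labels)
                 if t == cls and p == cls)
        fn = sum(1 for t, p in zip(true_labels, predicted_labels)
                 if t == cls and p != cls)
        fp = sum(1 for t, p in zip(true_labels, predicted_labels)
                 if t != cls and p == cls)
        out.append(ConfusionCounts(cls, TP=tp, TN=n - tp - fn - fp, FP=fp, FN=fn))
    return out


def confusion_matrix_3x3(true_labels, predicted_labels) -> np.ndarray:
    """Rows = true class, columns = predicted class, order :data:`CLASSES`."""
    m = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for t, p in zip(list(true_labels), list(predicted_labels)):
        m[CLASSES.index(t), CLASSES.index(p)] += 1
    return m


def _ratio(num: float, den: float, what: str, cls: str) -> float:
    if den == 0:
        warnings.warn(
            f"{what} undefined for class {cls} (zero denominator); reported as NaN",
            RuntimeWarning,
            stacklevel=3,
        )
        return float("nan")
    return num / den


def compute_metrics(counts: list[ConfusionCounts]) -> MetricsReport:
    """Six metrics per class (fractions in [0, 1]) plus their macro averages."""
    per_class: dict[str, dict[str, float]] = {}
    n_eval = counts[0].total if counts else 0
    for c in counts:
        precision = _ratio(c.TP, c.TP + c.FP, "precision", c.class_label)
        recall = _ratio(c.TP, c.TP + c.FN, "recall", c.class_label)
        if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
            f = (float("nan") if np.isnan(precision) or np.isnan(recall)
                 else _ratio(0.0, 0.0, "f_measure", c.class_label))
        else:
            f = 2.0 * precision * recall / (precision + recall)
        per_class[c.class_label] = {
            "accuracy": _ratio(c.TP + c.TN, c.total, "accuracy", c.class_label),
            "precision": precision,
            "recall": recall,
            "f_measure": f,
            "sensitivity": recall,  # same formula by construction
            "specificity": _ratio(c.TN, c.TN + c.FP, "specificity", c.class_label),
        }
    report = MetricsReport(per_class=per_class, macro={}, n_eval=n_eval,
                           counts=list(counts))
    report.macro = macro_average(report)
    return report


def macro_average(report: MetricsReport) -> dict[str, float]:
    """Unweighted arithmetic mean of each metric over classes."""
    if not report.per_class:
        raise ValueError("report has no classes")
    return {
        m: float(np.mean([v[m] for v in report.per_class.values()]))
        for m in METRIC_NAMES
    }


def render_confusion_figure(counts_3x3, out_path) -> None:
    """Save a labeled heatmap of a 3x3 confusion matrix (rows = true)."""
    m = np.asarray(counts_3x3)
    if m.shape != (3, 3) or not np.issubdtype(m.dtype, np.integer):
        raise ValueError("expected a 3x3 integer matrix")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(m, cmap="Blues")
    ax.set_xticks(range(3), CLASSES)
    ax.set_yticks(range(3), CLASSES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(3):
        for j in range(3):
            ax.text(j, i, str(m[i, j]), ha="center", va="center",
                    color="black" if m[i, j] < m.max() / 2 else "white")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
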