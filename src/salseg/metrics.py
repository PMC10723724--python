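"""Confusion counts and the five segmentation quality metrics.

Dice (DSC), accuracy, specificity, Jaccard and F1, all derived from the
per-pixel confusion counts of a predicted mask against ground truth.
DSC and F1 share the formula 2TP / (2TP + FP + FN) and are reported
separately only for table compatibility.  A metric whose denominator is
zero is reported as missing (None), never coerced to 0 or 1, so that
averages over image sets are not silently corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .image_io import validate_mask

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "compute_metrics", "METRIC_NAMES"]

METRIC_NAMES = ("dsc", "accuracy", "specificity", "jaccard", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five metrics; None marks an undefined (zero-denominator) value."""

    dsc: float | None
    accuracy: float | None
    specificity: float | None
    jaccard: float | None
    f1: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel tally of a predicted {0,1} mask against ground truth."""
    pred = validate_mask(pred)
    truth = validate_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(
            f"mask shapes differ: pred {pred.shape} vs truth {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Dice, accuracy, specificity, Jaccard and F1 from confusion counts.

    DSC = 2TP/(2TP+FP+FN); Accuracy = (TP+TN)/total;
    Specificity = TN/(TN+FP); Jaccard = TP/(TP+FP+FN); F1 = DSC.
    """
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    dice = _ratio(2.0 * tp, 2.0 * tp + fp + fn)
    return MetricsReport(
        dsc=dice,
        accuracy=_ratio(tp + tn, counts.total),
        specificity=_ratio(tn, tn + fp),
        jaccard=_ratio(tp, tp + fp + fn),
        f1=dice,
    )
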