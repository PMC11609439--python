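"""Confusion-matrix segmentation metrics.

Per-pixel binary evaluation with the nucleus class as positive:

    Acc    = (TP + TN) / total
    Pre    = TP / (TP + FP)
    Recall = TP / (TP + FN)
    IOU    = TP / (TP + FP + FN)
    DSC    = 2 TP / (2 TP + FP + FN)

IOU and DSC are the intersection-over-union and Dice coefficient of the
predicted and true foreground regions; DSC = 2*IOU / (1 + IOU) always.
Ratios with a zero denominator (e.g. an empty-foreground image predicted
empty) score 1 by convention and are flagged as degenerate rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricsReport", "confusion",
           "compute_metrics", "aggregate", "metrics_frame"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self):
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    pre: float
    recall: float
    iou: float
    dsc: float
    degenerate: bool = False

    def asdict(self):
        return asdict(self)


def confusion(pred, truth, positive_class=1):
    """Per-pixel confusion counts with ``positive_class`` as YES."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    p = pred == positive_class
    t = truth == positive_class
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num, den):
    """num/den, or (1.0, degenerate) when the denominator is zero."""
    if den == 0:
        return 1.0, True
    return num / den, False


def compute_metrics(c):
    """Derive the five metrics from confusion counts."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = (c.tp + c.tn) / c.total
    pre, d1 = _ratio(c.tp, c.tp + c.fp)
    rec, d2 = _ratio(c.tp, c.tp + c.fn)
    iou, d3 = _ratio(c.tp, c.tp + c.fp + c.fn)
    dsc, d4 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return MetricsReport(acc=acc, pre=pre, recall=rec, iou=iou, dsc=dsc,
                         degenerate=d1 or d2 or d3 or d4)


def aggregate(pairs, positive_class=1):
    """Pooled and per-image-mean metrics over (pred, truth) pairs.

    Returns (pooled: MetricsReport, per_image: list[MetricsReport],
    mean: dict, std: dict).  Pooled metrics come from summing confusion
    counts over all pixels of all images; the per-image mean (the default
    headline number) averages each metric over images.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty dataset")
    counts = [confusion(p, t, positive_class) for p, t in pairs]
    pooled = compute_metrics(sum(counts[1:], counts[0]))
    per_image = [compute_metrics(c) for c in counts]
    keys = ("acc", "pre", "recall", "iou", "dsc")
    arr = {k: np.array([getattr(r, k) for r in per_image]) for k in keys}
    mean = {k: float(v.mean()) for k, v in arr.items()}
    std = {k: float(v.std()) for k, v in arr.items()}
    return pooled, per_image, mean, std


def metrics_frame(per_image, mean, std):
    """One row per image plus a summary row, Table-style mean +/- std."""
    rows = [r.asdict() for r in per_image]
    df = pd.DataFrame(rows)
    df.insert(0, "image", range(len(rows)))
    summary = {"image": "mean±std", "degenerate": ""}
    for k in ("acc", "pre", "recall", "iou", "dsc"):
        summary[k] = f"{mean[k]:.4f}±{std[k]:.4f}"
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
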