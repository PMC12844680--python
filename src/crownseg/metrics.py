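"""Pixel-level segmentation metrics: IoU, PA, Precision, Recall, F1, mIoU.

All ratios are reported as percentages.  The crown class (1) is the positive
class.  Undefined ratios (zero denominator) are returned as ``nan`` rather
than silently 0; dataset-level aggregation is *micro* — pixel counts are
pooled over tiles first, then ratios computed once — which sidesteps
per-tile undefined values (tiles with neither positive labels nor positive
predictions still contribute their TN counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion",
    "iou",
    "pa",
    "precision",
    "recall",
    "f1",
    "background_counts",
    "mean_iou",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion(pred: np.ndarray, label: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion tally with crown (1) as the positive class."""
    pred = np.asarray(pred)
    label = np.asarray(label)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs label {label.shape}")
    for name, arr in (("pred", pred), ("label", label)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (values in {{0, 1}})")
    p = pred.astype(bool)
    l = label.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & l)),
        fp=int(np.count_nonzero(p & ~l)),
        fn=int(np.count_nonzero(~p & l)),
        tn=int(np.count_nonzero(~p & ~l)),
    )


def _ratio(num: float, den: float) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def iou(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def pa(c: ConfusionCounts) -> float:
    """Pixel accuracy over both classes."""
    return _ratio(c.tp + c.tn, c.n)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    if np.isnan(p) or np.isnan(r) or p + r == 0:
        return float("nan")
    return 2.0 * p * r / (p + r)


def background_counts(c: ConfusionCounts) -> ConfusionCounts:
    """Confusion counts with the class labels swapped (background positive)."""
    return ConfusionCounts(tp=c.tn, fp=c.fn, fn=c.fp, tn=c.tp)


def mean_iou(c0: ConfusionCounts, c1: ConfusionCounts) -> float:
    """Unweighted mean of the background and crown IoUs.

    A class whose IoU is undefined is skipped; if both are undefined the
    result is ``nan``.
    """
    vals = [v for v in (iou(c0), iou(c1)) if not np.isnan(v)]
    return float("nan") if not vals else float(np.mean(vals))


def metrics_row(c: ConfusionCounts) -> dict:
    return {
        "IoU": iou(c),
        "PA": pa(c),
        "Precision": precision(c),
        "Recall": recall(c),
        "F1": f1(c),
        "mIoU": mean_iou(background_counts(c), c),
    }


def evaluate_dataset(model, samples) -> dict:
    """Micro-aggregated report over tiles, plus per-tile metric rows.

    ``model`` must expose ``predict_mask(rgb, ms) -> (H, W) {0,1}``.
    Returns ``{"pooled": {...}, "per_tile": DataFrame, "counts": ConfusionCounts}``.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("evaluate_dataset requires a non-empty sample list")
    pooled = ConfusionCounts(0, 0, 0, 0)
    rows = []
    for i, sample in enumerate(samples):
        pred = model.predict_mask(sample.rgb, sample.ms)
        c = confusion(pred, sample.mask)
        pooled = pooled + c
        row = {"tile": sample.meta.get("id", f"tile_{i:04d}")}
        row.update(metrics_row(c))
        rows.append(row)
    return {
        "pooled": metrics_row(pooled),
        "per_tile": pd.DataFrame(rows),
        "counts": pooled,
    }
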