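"""Pixel-level evaluation indices for binary segmentation.

Six indices derive from the (TP, TN, FP, FN) contingency counts: pixel
accuracy PA, pixel recall PR, pixel precision PP, pixel specificity PS,
intersection-over-union IoU, and the F1 score.  Dataset-level scores are
per-image means (mIoU etc.); pooled-count aggregation is also exposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ContingencyCounts",
    "MetricReport",
    "contingency",
    "compute_metrics",
    "evaluate_pair",
    "aggregate",
    "report_to_csv",
    "report_to_json",
]

METRIC_NAMES = ("PA", "PR", "PP", "PS", "IoU", "F1")


@dataclass(frozen=True)
class ContingencyCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ContingencyCounts") -> "ContingencyCounts":
        return ContingencyCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricReport:
    PA: float
    PR: float
    PP: float
    PS: float
    IoU: float
    F1: float

    def as_dict(self) -> dict:
        return asdict(self)

    def as_percent(self, decimals: int = 2) -> dict:
        return {k: round(100.0 * v, decimals) for k, v in self.as_dict().items()}


def _binarize(mask, threshold: float = 0.5) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype.kind == "f" and not np.isin(np.unique(arr), (0.0, 1.0)).all():
        arr = (arr >= threshold).astype(np.uint8)
    else:
        arr = arr.astype(np.uint8)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError("mask is not binary after thresholding")
    return arr


def contingency(pred, truth, threshold: float = 0.5) -> ContingencyCounts:
    """Per-pixel TP/TN/FP/FN tallies; probability inputs are thresholded."""
    p = _binarize(pred, threshold)
    t = _binarize(truth, threshold)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t & 1))
    fn = int(np.count_nonzero(~p & 1 & t))
    tn = p.size - tp - fp - fn
    return ContingencyCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int, counterpart_empty: bool) -> float:
    """num/den with the empty-set convention: 1 when both sides are empty."""
    if den == 0:
        return 1.0 if counterpart_empty else 0.0
    return num / den


def compute_metrics(c: ContingencyCounts) -> MetricReport:
    """The six indices from one set of counts.

    Degenerate denominators follow the empty-set convention: an index whose
    denominator is zero is 1 if the counterpart set is also empty, else 0.
    """
    if c.total == 0:
        raise ValueError("empty contingency table")
    pa = (c.tp + c.tn) / c.total
    pr = _ratio(c.tp, c.tp + c.fn, counterpart_empty=c.fp == 0)
    pp = _ratio(c.tp, c.tp + c.fp, counterpart_empty=c.fn == 0)
    ps = _ratio(c.tn, c.tn + c.fp, counterpart_empty=c.fn == 0)
    iou = _ratio(c.tp, c.tp + c.fp + c.fn, counterpart_empty=True)
    if pr + pp > 0:
        f1 = 2.0 * pr * pp / (pr + pp)
    else:
        f1 = 1.0 if (c.tp + c.fp + c.fn) == 0 else 0.0
    return MetricReport(pa, pr, pp, ps, iou, f1)


def evaluate_pair(pred, truth, threshold: float = 0.5) -> MetricReport:
    return compute_metrics(contingency(pred, truth, threshold))


def aggregate(reports: list, mode: str = "per_image") -> MetricReport:
    """Dataset-level scores.

    ``per_image`` (default) averages each index across images, matching the
    mean-IoU convention; ``pooled`` sums counts first (requires
    ContingencyCounts inputs).
    """
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    if mode == "per_image":
        vals = {
            name: float(np.mean([getattr(r, name) for r in reports]))
            for name in METRIC_NAMES
        }
        return MetricReport(**vals)
    if mode == "pooled":
        total = reports[0]
        for c in reports[1:]:
            total = total + c
        return compute_metrics(total)
    raise ValueError("mode must be 'per_image' or 'pooled'")


def report_to_csv(reports: dict, path) -> None:
    """Write named reports as CSV on the 0-100 (%) scale, two decimals."""
    import pandas as pd

    rows = {name: r.as_percent() for name, r in reports.items()}
    pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)].to_csv(
        path, index_label="id", float_format="%.2f"
    )


def report_to_json(reports: dict, path) -> None:
    payload = {name: r.as_percent() for name, r in reports.items()}
    Path(path).write_text(json.dumps(payload, indent=2))
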