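"""Segmentation validation metrics against ground-truth masks.

Per-pixel confusion counts feed sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and accuracy (TP+TN)/total; overlap is measured by the Jaccard
index |A∩B|/|A∪B| and boundary agreement by the Hausdorff distance between
foreground point sets (directed max-min form, plus the symmetric
max-of-both-directions form that segmentation validation conventionally
reports).  Segmented area is the foreground pixel count, and the
intra-observer true-positive rate applies the sensitivity formula pairwise
between two raters' masks.  Cohort tables are summarized by mean, sample
(n-1) standard deviation and coefficient of variation sd/mean.

Metrics whose denominator vanishes raise ``UndefinedMetricError``; report
writers record them as missing values, never as silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "MetricsReport",
    "Summary",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "jaccard",
    "hausdorff",
    "segmented_area",
    "intra_observer_tpr",
    "summarize",
    "evaluate_mask",
]


class UndefinedMetricError(ValueError):
    """The metric's denominator is zero for these inputs."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    jaccard: float
    hausdorff: float
    area_pred: int
    area_truth: int


@dataclass(frozen=True)
class Summary:
    mean: float
    sd: float
    cv: float


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts with foreground = ligament."""
    pred, truth = _as_bool(pred), _as_bool(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: zero denominator")
    return num / den


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two masks (undefined when both empty)."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise UndefinedMetricError("jaccard undefined: both masks empty")
    return np.count_nonzero(a & b) / union


def hausdorff(a: np.ndarray, b: np.ndarray, mode: str = "symmetric") -> float:
    """Hausdorff distance between foreground point sets (Euclidean).

    ``mode="directed"`` is max_{p in A} min_{q in B} ||p - q||;
    ``mode="symmetric"`` (the reporting default) is the max of the two
    directed distances.
    """
    if mode not in ("directed", "symmetric"):
        raise ValueError("mode must be 'directed' or 'symmetric'")
    pa = np.argwhere(_as_bool(a))
    pb = np.argwhere(_as_bool(b))
    if len(pa) == 0 or len(pb) == 0:
        raise UndefinedMetricError("hausdorff undefined: empty mask")
    d_ab = directed_hausdorff(pa, pb)[0]
    if mode == "directed":
        return float(d_ab)
    return float(max(d_ab, directed_hausdorff(pb, pa)[0]))


def segmented_area(mask: np.ndarray) -> int:
    """Foreground pixel count."""
    return int(np.count_nonzero(_as_bool(mask)))


def intra_observer_tpr(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """True-positive rate of ``mask_x`` treating ``mask_y`` as truth —
    the pairwise inter-rater reliability measure (note: asymmetric)."""
    return sensitivity(confusion(mask_x, mask_y))


def summarize(values) -> Summary:
    """Mean, sample (n-1) standard deviation, and coefficient of variation."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size < 2:
        raise ValueError("summarize needs at least two values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean == 0:
        raise UndefinedMetricError("cv undefined: zero mean")
    return Summary(mean=mean, sd=sd, cv=sd / mean)


def evaluate_mask(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Full per-image report; undefined entries are recorded as NaN."""
    c = confusion(pred, truth)

    def _try(fn, *args):
        try:
            return fn(*args)
        except UndefinedMetricError:
            return math.nan

    return MetricsReport(
        sensitivity=_try(sensitivity, c),
        specificity=_try(specificity, c),
        accuracy=_try(accuracy, c),
        jaccard=_try(jaccard, pred, truth),
        hausdorff=_try(hausdorff, pred, truth),
        area_pred=segmented_area(pred),
        area_truth=segmented_area(truth),
    )
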