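"""Per-image segmentation metrics and the statistics used to compare models.

Five pixel-level metrics are computed from the confusion counts of a
predicted binary atrophy mask against a reference mask: accuracy,
sensitivity, specificity, Dice coefficient and intersection-over-union
(IoU).  Model comparisons are summarized as percent differences
``(m2 - m1) / m1`` of aggregated metrics, Mann-Whitney U tests on the
per-image samples, and normal-quantile 95% confidence intervals
(half-width ``1.959964 * sd / sqrt(n)``, matching the common spreadsheet
``CONFIDENCE`` function; a Student-t variant is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "MannWhitneyResult",
    "confusion_counts",
    "compute_metrics",
    "evaluate_pair",
    "percent_difference",
    "mann_whitney",
    "ci95",
    "summarize_metrics",
    "comparison_table",
]

#: Two-sided 97.5% standard-normal quantile, as used by spreadsheet CIs.
Z975 = 1.959964

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "dice", "iou")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts of a predicted mask against a reference."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    """The five evaluation metrics; undefined ratios are flagged.

    ``undefined`` maps a metric name to a short reason whenever its
    denominator vanished.  In the doubly-empty case (reference and
    prediction both contain no atrophy) dice, IoU and sensitivity are
    reported as 1.0 by convention -- a perfect prediction of a
    lesion-free image is not penalized -- and flagged so callers can
    exclude them from averages if they prefer.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    dice: float
    iou: float
    undefined: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _require_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(
            f"{name} must be binary (values in {{0, 1}}); found values {vals[:8]}"
        )
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/TN/FN pixels of ``pred`` against the reference ``gt``."""
    pred = _require_binary(pred, "pred")
    gt = _require_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Evaluate the five metrics from confusion counts.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), Dice = 2TP/(2TP+FP+FN),
    IoU = TP/(TP+FP+FN).  Vanishing denominators are flagged rather than
    silently zeroed; see :class:`MetricSet` for the doubly-empty
    convention.
    """
    undefined: dict = {}
    total = c.total
    if total == 0:
        raise ValueError("empty confusion counts: no pixels compared")
    accuracy = (c.tp + c.tn) / total

    both_empty = (c.tp + c.fn == 0) and (c.fp == 0)

    if c.tp + c.fn > 0:
        sensitivity = c.tp / (c.tp + c.fn)
    else:
        undefined["sensitivity"] = "reference contains no positive pixels"
        sensitivity = 1.0 if both_empty else math.nan

    if c.tn + c.fp > 0:
        specificity = c.tn / (c.tn + c.fp)
    else:
        undefined["specificity"] = "reference contains no negative pixels"
        specificity = math.nan

    if 2 * c.tp + c.fp + c.fn > 0:
        dice = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
        iou = c.tp / (c.tp + c.fp + c.fn)
    else:
        undefined["dice"] = "both masks empty (reported as 1 by convention)"
        undefined["iou"] = "both masks empty (reported as 1 by convention)"
        dice = 1.0
        iou = 1.0

    return MetricSet(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        dice=dice,
        iou=iou,
        undefined=undefined,
    )


def evaluate_pair(pred: np.ndarray, gt: np.ndarray) -> MetricSet:
    """Convenience wrapper: confusion counts then metrics."""
    return compute_metrics(confusion_counts(pred, gt))


def percent_difference(m1: float, m2: float) -> float:
    """Fractional difference (m2 - m1) / m1 of two aggregated metrics."""
    if m1 == 0:
        raise ValueError("percent difference undefined for a zero baseline metric")
    return (m2 - m1) / m1


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # U statistic of the first sample
    p_value: float    # two-sided
    method: str       # "exact" or "asymptotic"


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test on two independent samples.

    The exact null distribution is used when the combined sample size is
    at most 16 and there are no ties across the pooled sample; otherwise
    the normal approximation with tie correction and continuity
    correction is used.  The method actually applied is recorded in the
    result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 16 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue), method=method)


def ci95(values, quantile: str = "normal") -> tuple[float, float]:
    """Mean and 95% confidence half-width of a sample.

    ``quantile='normal'`` uses the z-quantile 1.959964 (the spreadsheet
    convention); ``quantile='t'`` uses the Student-t quantile with n-1
    degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("confidence interval requires at least 2 values")
    sd = float(np.std(values, ddof=1))
    if quantile == "normal":
        q = Z975
    elif quantile == "t":
        q = float(stats.t.ppf(0.975, df=n - 1))
    else:
        raise ValueError(f"unknown quantile kind: {quantile!r}")
    return float(np.mean(values)), q * sd / math.sqrt(n)


def summarize_metrics(per_image: pd.DataFrame, order: str = "images_then_folds") -> pd.DataFrame:
    """Aggregate per-image metrics into a per-metric summary table.

    ``per_image`` holds one row per test image with columns ``fold`` and
    the five metric names.  ``order='images_then_folds'`` averages across
    images within each fold and then across folds; ``order='pooled'``
    averages across all images at once.  Confidence half-widths are
    computed on the per-image samples either way (NaNs from undefined
    metrics are excluded).
    """
    rows = []
    for name in METRIC_NAMES:
        vals = per_image[name].dropna().to_numpy()
        if order == "images_then_folds":
            mean = float(per_image.groupby("fold")[name].mean().mean())
        elif order == "pooled":
            mean = float(vals.mean())
        else:
            raise ValueError(f"unknown aggregation order: {order!r}")
        _, hw = ci95(vals) if vals.size >= 2 else (math.nan, math.nan)
        rows.append({"metric": name, "mean": mean, "ci95_halfwidth": hw, "n_images": vals.size})
    return pd.DataFrame(rows)


def comparison_table(
    per_image_1: pd.DataFrame,
    per_image_2: pd.DataFrame,
    label_1: str = "model_1",
    label_2: str = "model_2",
    order: str = "images_then_folds",
) -> pd.DataFrame:
    """Model-comparison table from two models' per-image metric tables.

    Percent differences are computed on the unrounded aggregated means,
    Mann-Whitney on the per-image samples; half-widths of both samples
    are carried along.
    """
    s1 = summarize_metrics(per_image_1, order=order).set_index("metric")
    s2 = summarize_metrics(per_image_2, order=order).set_index("metric")
    rows = []
    for name in METRIC_NAMES:
        v1 = per_image_1[name].dropna().to_numpy()
        v2 = per_image_2[name].dropna().to_numpy()
        mw = mann_whitney(v1, v2)
        m1 = s1.loc[name, "mean"]
        rows.append(
            {
                "metric": name,
                f"mean_{label_1}": m1,
                f"mean_{label_2}": s2.loc[name, "mean"],
                "percent_difference": (
                    percent_difference(m1, s2.loc[name, "mean"])
                    if m1 != 0 else math.nan
                ),
                "p_value": mw.p_value,
                "mw_method": mw.method,
                f"ci95_{label_1}": s1.loc[name, "ci95_halfwidth"],
                f"ci95_{label_2}": s2.loc[name, "ci95_halfwidth"],
            }
        )
    return pd.DataFrame(rows)
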