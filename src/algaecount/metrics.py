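"""Validation arithmetic: count MAE, mask IoU, area error, agreement stats.

Detection quality is scored by the mean absolute error between true and
predicted per-image counts; segmentation quality by the Jaccard index
(intersection over union) of binary masks. Agreement between automated and
expert concentrations is summarized by the percentage difference (absolute
error relative to the expert value), Pearson correlation, and per-column
mean/median/population-SD summaries. A least-squares line of percentage
error on clump (agglomeration) rate quantifies how counting degrades as
cells stick together.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

from .detection import DetectionSet


def mae(true_counts: Sequence[float], predicted_counts: Sequence[float]) -> float:
    """Mean absolute error ``(1/N) * sum |x_i - y_i|`` over paired counts."""
    x = np.asarray(true_counts, dtype=float)
    y = np.asarray(predicted_counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("true and predicted counts must be equal-length, non-empty")
    return float(np.mean(np.abs(x - y)))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B| of two binary masks.

    Two empty masks agree perfectly (1.0); exactly one empty scores 0.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    inter = np.logical_and(a, b).sum()
    return float(inter / union)


def _mean_cell_area(obj) -> float:
    """Mean per-cell area: pi*r^2 for circle parameterizations, mean
    connected-component pixel count for masks."""
    if isinstance(obj, DetectionSet):
        radii = np.array([d.radius_px for d in obj.detections], dtype=float)
        if radii.size == 0:
            raise ValueError("no detections to take areas from")
        return float(np.mean(np.pi * radii**2))
    arr = np.asarray(obj)
    if arr.ndim == 2:  # binary mask
        from skimage import measure

        labels = measure.label(arr.astype(bool))
        n = labels.max()
        if n == 0:
            raise ValueError("mask has no foreground objects")
        return float(arr.astype(bool).sum() / n)
    radii = arr.astype(float).ravel()
    if radii.size == 0:
        raise ValueError("empty radius sequence")
    return float(np.mean(np.pi * radii**2))


def mean_area_error(predicted, truth) -> float:
    """Relative error of the mean cell area, in percent.

    ``predicted`` and ``truth`` may each be a :class:`DetectionSet`, a
    sequence of radii, or a binary mask.
    """
    pa = _mean_cell_area(predicted)
    ta = _mean_cell_area(truth)
    return float(abs(pa - ta) / ta * 100.0)


def percentage_difference(expert: float, automatic: float) -> float:
    """Absolute automated-vs-expert error as a percentage of the expert value."""
    if expert <= 0:
        raise ValueError("expert value must be positive")
    return float(abs(automatic - expert) / expert * 100.0)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length sequences of at least 2 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


def column_summary(values: Sequence[float]) -> tuple[float, float, float]:
    """(mean, median, population SD) of a column of values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty column")
    return float(arr.mean()), float(np.median(arr)), float(arr.std(ddof=0))


def agglomeration_trend(
    rates: Sequence[float], pct_errors: Sequence[float]
) -> tuple[float, float]:
    """OLS fit of percentage error on agglomeration rate -> (slope, intercept)."""
    r = np.asarray(rates, dtype=float)
    e = np.asarray(pct_errors, dtype=float)
    if r.shape != e.shape or r.size < 2:
        raise ValueError("need equal-length sequences of at least 2 values")
    if np.std(r) == 0:
        raise ValueError("agglomeration rates must vary")
    slope, intercept = np.polyfit(r, e, 1)
    return float(slope), float(intercept)


def ks_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (convenience; statistic, p-value)."""
    res = sps.ks_2samp(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)
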