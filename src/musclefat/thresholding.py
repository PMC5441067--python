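"""Fat/muscle threshold selection by Otsu's method within the ROI.

Pixel intensities are normalized to [0, 1]; the threshold maximizing the
between-class variance of a two-class split of the ROI histogram separates
T2-bright fat (above threshold) from darker lean muscle (at or below).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_config import GrayImage
from .roi import BinaryMask

__all__ = ["ThresholdResult", "otsu_threshold", "classify_fat"]


@dataclasses.dataclass
class ThresholdResult:
    """Selected threshold on the normalized [0, 1] intensity scale."""

    threshold: float
    between_class_variance: float
    histogram: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")
        if self.between_class_variance < 0:
            raise ValueError("between-class variance must be >= 0")


def otsu_threshold(intensities, n_bins: int = 256) -> ThresholdResult:
    """Otsu threshold of a list of normalized intensities.

    Builds an ``n_bins`` equal-width histogram on [0, 1] and scans every
    interior bin boundary ``t = k / n_bins``, maximizing the between-class
    variance ``sigma_B^2(t) = w0 * w1 * (mu0 - mu1)^2`` where class 0 is the
    bins below ``t``.  Bin-center intensities are used for the class means.
    Ties are broken toward the smallest ``t``; the returned threshold is the
    upper edge of the optimal lower-class bin range.

    A constant input is degenerate: the threshold is that value itself with
    zero between-class variance, and downstream classification (strictly
    greater than the threshold is fat) assigns every pixel to muscle.
    """
    vals = np.asarray(intensities, dtype=float).ravel()
    if vals.size < 2:
        raise ValueError("need at least 2 intensity values")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("intensities must be normalized to [0, 1]")
    hist, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    if vals.min() == vals.max():
        return ThresholdResult(float(vals[0]), 0.0, hist, degenerate=True)

    p = hist / hist.sum()
    centers = (np.arange(n_bins) + 0.5) / n_bins
    w0 = np.cumsum(p)[:-1]  # class 0 = bins 0..k-1 for boundary k = 1..n_bins-1
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * centers)[:-1]
    mu = cum_mean[-1] + p[-1] * centers[-1]  # grand mean
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, cum_mean / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu - cum_mean) / w1, 0.0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(sigma_b))  # argmax takes the first (smallest t) on ties
    return ThresholdResult((k + 1) / n_bins, float(sigma_b[k]), hist)


def classify_fat(img: GrayImage, mask: BinaryMask, thr: ThresholdResult) -> BinaryMask:
    """Partition ROI pixels into fat (bright) and muscle by the threshold.

    Fat pixels are those whose normalized intensity is *strictly* greater
    than the threshold; the muscle mask is the complement within the ROI, so
    fat count + muscle count equals the ROI count exactly.
    """
    if mask.count == 0:
        raise ValueError("empty ROI mask")
    if mask.shape != (img.height, img.width):
        raise ValueError("mask shape does not match image")
    fat = mask.bits & (img.normalized() > thr.threshold)
    return BinaryMask(fat)
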