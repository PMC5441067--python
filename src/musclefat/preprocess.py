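"""Contrast enhancement: CLAHE followed by tail-saturating stretching.

The two stages mirror the preprocessing used before intensity thresholding
of T2-weighted slices: adaptive histogram equalization applied per image
tile (with histogram clipping and bilinear blending of tile mappings to
avoid tile-boundary artifacts), then a global contrast stretch that
saturates a small fraction of the darkest and brightest pixels.  Both
stages exist to flatten slow multiplicative intensity bias so that a single
fat/muscle threshold is meaningful across the whole region of interest.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .io_config import GrayImage

__all__ = ["ClaheParams", "AdjustParams", "clahe", "stretch_contrast", "preprocess_slice"]


@dataclasses.dataclass(frozen=True)
class ClaheParams:
    """CLAHE settings.

    ``clip_limit`` is relative: the per-tile histogram is clipped at
    ``clip_limit`` times the uniform bin height (tile pixel count / n_bins).
    ``clip_limit = math.inf`` disables clipping, reducing each tile to plain
    histogram equalization.
    """

    tile_rows: int = 8
    tile_cols: int = 8
    clip_limit: float = 2.0
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError("tile grid must be >= 1 in each direction")
        if not (self.clip_limit >= 1.0):
            raise ValueError("clip_limit must be >= 1 (or inf for unclipped)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclasses.dataclass(frozen=True)
class AdjustParams:
    """Tail saturation fractions for the contrast stretch (per tail)."""

    low_saturation_fraction: float = 0.01
    high_saturation_fraction: float = 0.01

    def __post_init__(self) -> None:
        for f in (self.low_saturation_fraction, self.high_saturation_fraction):
            if not (0.0 <= f < 0.5):
                raise ValueError("saturation fractions must lie in [0, 0.5)")
        if self.low_saturation_fraction + self.high_saturation_fraction >= 1:
            raise ValueError("saturation fractions must sum to < 1")


def _tile_edges(extent: int, n_tiles: int) -> np.ndarray:
    """Integer tile boundaries: rounded equal partition, last tile absorbs
    the remainder."""
    return np.round(np.linspace(0, extent, n_tiles + 1)).astype(int)


def _clip_histogram(hist: np.ndarray, clip_limit: float, n_pixels: int) -> np.ndarray:
    """Clip bins at clip_limit x uniform height; spread the excess evenly."""
    if not math.isfinite(clip_limit):
        return hist.astype(float)
    ceiling = clip_limit * n_pixels / hist.size
    clipped = np.minimum(hist, ceiling).astype(float)
    excess = float(hist.sum() - clipped.sum())
    return clipped + excess / hist.size


def clahe(img: GrayImage, params: ClaheParams = ClaheParams()) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    The image is split into ``tile_rows x tile_cols`` rectangles.  Each
    tile's ``n_bins`` histogram is clipped and turned into an equalization
    lookup table (its CDF rescaled onto ``[0, L-1]``).  Every output pixel is
    the bilinear blend of the lookup tables of its (up to four) nearest tile
    centers; pixels beyond the outermost centers clamp to the edge tiles.
    """
    h, w = img.height, img.width
    tr, tc, nb = params.tile_rows, params.tile_cols, params.n_bins
    if tr > h or tc > w:
        raise ValueError(f"tile grid {tr}x{tc} larger than image {h}x{w}")
    L = img.levels
    pix = np.asarray(img.pixels, dtype=float)
    # bin index of every pixel on the [0, L-1] range
    bins = np.clip((pix * nb / L).astype(int), 0, nb - 1)

    row_edges = _tile_edges(h, tr)
    col_edges = _tile_edges(w, tc)
    luts = np.empty((tr, tc, nb), dtype=float)
    for i in range(tr):
        for j in range(tc):
            tile = bins[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=nb)
            clipped = _clip_histogram(hist, params.clip_limit, tile.size)
            cdf = np.cumsum(clipped)
            luts[i, j] = cdf / cdf[-1] * (L - 1)

    ctr_r = (row_edges[:-1] + row_edges[1:]) / 2.0 - 0.5
    ctr_c = (col_edges[:-1] + col_edges[1:]) / 2.0 - 0.5
    i1, wr = _blend_coords(np.arange(h, dtype=float), ctr_r)
    j1, wc = _blend_coords(np.arange(w, dtype=float), ctr_c)
    i0 = np.maximum(i1 - 1, 0)
    j0 = np.maximum(j1 - 1, 0)

    I0, J0 = np.meshgrid(i0, j0, indexing="ij")
    I1, J1 = np.meshgrid(i1, j1, indexing="ij")
    WR = wr[:, None]
    WC = wc[None, :]
    out = (
        (1 - WR) * (1 - WC) * luts[I0, J0, bins]
        + (1 - WR) * WC * luts[I0, J1, bins]
        + WR * (1 - WC) * luts[I1, J0, bins]
        + WR * WC * luts[I1, J1, bins]
    )
    return GrayImage(np.clip(out, 0, L - 1), levels=L)


def _blend_coords(coords: np.ndarray, centers: np.ndarray):
    """Upper-neighbor index and its weight for 1-D center interpolation.

    Returns ``(i1, w)`` such that the blend along this axis is
    ``(1 - w) * mapping[i1 - 1] + w * mapping[i1]`` (with ``i1 - 1`` clamped
    to 0 by the caller).  Coordinates outside the first/last center clamp to
    weight 0 or 1, i.e. use the single edge mapping.
    """
    n = centers.size
    if n == 1:
        return np.zeros(coords.size, dtype=int), np.ones(coords.size)
    i1 = np.searchsorted(centers, coords, side="left")
    i1 = np.clip(i1, 1, n - 1)
    span = centers[i1] - centers[i1 - 1]
    w = np.clip((coords - centers[i1 - 1]) / span, 0.0, 1.0)
    return i1, w


def stretch_contrast(img: GrayImage, params: AdjustParams = AdjustParams()) -> GrayImage:
    """Saturating linear contrast stretch.

    Maps the ``[lo, hi]`` intensity window onto the full ``[0, L-1]`` range,
    where ``lo``/``hi`` are the low/high saturation quantiles of the pixel
    intensities (linear interpolation between order statistics).  Intensities
    at or below ``lo`` go to 0, at or above ``hi`` to ``L-1``.  A constant or
    near-constant image (``lo == hi``) is returned unchanged with a warning.
    """
    L = img.levels
    pix = np.asarray(img.pixels, dtype=float)
    lo = float(np.quantile(pix, params.low_saturation_fraction))
    hi = float(np.quantile(pix, 1.0 - params.high_saturation_fraction))
    if hi <= lo:
        warnings.warn(
            "contrast stretch skipped: saturation quantiles coincide "
            "(constant or near-constant image)",
            stacklevel=2,
        )
        return GrayImage(pix.copy(), levels=L)
    out = np.clip((pix - lo) / (hi - lo), 0.0, 1.0) * (L - 1)
    return GrayImage(out, levels=L)


def preprocess_slice(
    img: GrayImage,
    clahe_params: ClaheParams = ClaheParams(),
    adjust_params: AdjustParams = AdjustParams(),
) -> GrayImage:
    """Full preprocessing: CLAHE, then the saturating contrast stretch."""
    return stretch_contrast(clahe(img, clahe_params), adjust_params)
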