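"""Polygon regions of interest and their raster masks.

The manual muscle outline is an ordered vertex list in pixel coordinates
(``(x, y) = (column, row)``, 0-based, pixel centers at integers).  A pixel
belongs to the rasterized region iff its center is inside the polygon under
the even-odd rule, with the half-open convention for centers falling exactly
on an edge (a center on an edge counts as inside iff the edge is crossed by
the upward half-open ray test, i.e. "lower/left" edges belong to the
polygon).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from shapely.geometry import LineString

__all__ = ["PolygonROI", "BinaryMask", "rasterize", "crop", "shoelace_area"]


@dataclasses.dataclass
class PolygonROI:
    """A simple (non-self-intersecting), implicitly closed polygon."""

    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) >= 2 and self.vertices[0] == self.vertices[-1]:
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 3:
            raise ValueError(f"polygon needs >= 3 vertices, got {len(self.vertices)}")

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.vertices, dtype=float)
        return arr[:, 0], arr[:, 1]

    def is_simple(self) -> bool:
        ring = LineString(self.vertices + self.vertices[:1])
        return ring.is_simple

    def translated(self, dx: float, dy: float) -> "PolygonROI":
        return PolygonROI([(x + dx, y + dy) for x, y in self.vertices])


@dataclasses.dataclass
class BinaryMask:
    """A boolean raster the same shape as its parent image."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def count(self) -> int:
        return int(self.bits.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row_min, row_max, col_min, col_max), inclusive, of true pixels."""
        rows, cols = np.nonzero(self.bits)
        if rows.size == 0:
            raise ValueError("empty mask has no bounding box")
        return int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())


def shoelace_area(poly: PolygonROI) -> float:
    """Continuous polygon area in pixel^2 units (diagnostic only).

    Tissue areas in this package are pixel counts; the shoelace area is
    exposed to sanity-check a traced outline against its raster count.
    """
    x, y = poly.xy()
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def rasterize(poly: PolygonROI, height: int, width: int) -> BinaryMask:
    """Rasterize a polygon to the pixel-center even-odd mask.

    For each pixel center an upward ray-crossing count is taken over the
    polygon edges using the half-open rule ``y1 <= y < y2`` (per edge,
    oriented by increasing y), which both implements the even-odd rule and
    breaks boundary ties deterministically.
    """
    if not poly.is_simple():
        raise ValueError("self-intersecting polygon")
    x, y = poly.xy()
    if x.max() < -0.5 or x.min() > width - 0.5 or y.max() < -0.5 or y.min() > height - 0.5:
        warnings.warn("polygon entirely outside image; mask is empty", stacklevel=2)
        return BinaryMask(np.zeros((height, width), dtype=bool))

    # Restrict the crossing test to the polygon's bounding box rows/cols.
    r0 = max(0, int(np.ceil(y.min())))
    r1 = min(height - 1, int(np.floor(y.max())))
    c0 = max(0, int(np.ceil(x.min())))
    c1 = min(width - 1, int(np.floor(x.max())))
    bits = np.zeros((height, width), dtype=bool)
    if r1 < r0 or c1 < c0:
        warnings.warn("polygon too thin to cover any pixel center", stacklevel=2)
        return BinaryMask(bits)

    px = np.arange(c0, c1 + 1, dtype=float)
    py = np.arange(r0, r1 + 1, dtype=float)
    X, Y = np.meshgrid(px, py)
    inside = np.zeros(X.shape, dtype=bool)
    n = len(x)
    for i in range(n):
        x1, y1 = x[i], y[i]
        x2, y2 = x[(i + 1) % n], y[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edges never satisfy the half-open y test
        cond = (Y >= min(y1, y2)) & (Y < max(y1, y2))
        # x-coordinate where the edge crosses the pixel row
        xi = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (X < xi)
    bits[r0 : r1 + 1, c0 : c1 + 1] = inside
    if not bits.any():
        warnings.warn("polygon covers no pixel center; mask is empty", stacklevel=2)
    return BinaryMask(bits)


def crop(img, mask: BinaryMask):
    """Restrict an image and its mask to the mask's bounding box.

    Pixel values outside the mask but inside the box are preserved in the
    cropped image; the cropped mask marks them false.
    """
    from .io_config import GrayImage

    if mask.count == 0:
        raise ValueError("cannot crop with an empty mask")
    if mask.shape != (img.height, img.width):
        raise ValueError("mask shape does not match image")
    r0, r1, c0, c1 = mask.bounding_box()
    sub = np.asarray(img.pixels)[r0 : r1 + 1, c0 : c1 + 1]
    return (
        GrayImage(sub.copy(), levels=img.levels),
        BinaryMask(mask.bits[r0 : r1 + 1, c0 : c1 + 1].copy()),
    )
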