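"""Image, ROI, measurement-table and configuration I/O.

Coordinate convention used throughout the package: pixel ``(x, y)`` means
``(column, row)``, 0-based, with the pixel's *center* at integer
coordinates.  Pixel ``(0, 0)`` therefore covers the continuous square
``[-0.5, 0.5] x [-0.5, 0.5]``.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "GrayImage",
    "PixelGeometry",
    "read_image",
    "write_image",
    "geometry_from_matrix",
    "read_roi",
    "write_roi",
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "read_config",
]

MEASUREMENT_COLUMNS = [
    "subject_id",
    "slice_id",
    "muscle",
    "side",
    "level",
    "csa_cm2",
    "fcsa_cm2",
    "fat_csa_cm2",
    "fat_fraction",
    "threshold",
]


@dataclasses.dataclass
class GrayImage:
    """A 2-D grayscale raster with an explicit number of gray levels.

    ``pixels`` holds non-negative intensities in ``[0, levels - 1]``; the
    dtype may be integer (as decoded from disk) or float (mid-pipeline).
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise ValueError("zero-size image")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        lo = float(self.pixels.min())
        hi = float(self.pixels.max())
        if lo < 0 or hi > self.levels - 1:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {self.levels - 1}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def normalized(self) -> np.ndarray:
        """Intensities rescaled to [0, 1] by dividing by ``levels - 1``."""
        return np.asarray(self.pixels, dtype=float) / (self.levels - 1)


@dataclasses.dataclass(frozen=True)
class PixelGeometry:
    """In-plane pixel spacing in millimetres."""

    row_spacing_mm: float
    col_spacing_mm: float

    def __post_init__(self) -> None:
        if self.row_spacing_mm <= 0 or self.col_spacing_mm <= 0:
            raise ValueError("pixel spacings must be strictly positive")

    @property
    def pixel_area_mm2(self) -> float:
        return self.row_spacing_mm * self.col_spacing_mm


def geometry_from_matrix(
    matrix_rows: int,
    matrix_cols: int,
    fov_rows_mm: float,
    fov_cols_mm: float,
) -> PixelGeometry:
    """Derive pixel spacing from acquisition matrix size and field of view.

    The spacing along each axis is FOV extent divided by the matrix size,
    e.g. a 256 x 256 matrix over a 256 mm x 256 mm FOV gives 1 mm pixels.
    """
    if matrix_rows <= 0 or matrix_cols <= 0:
        raise ValueError("matrix size must be strictly positive")
    if fov_rows_mm <= 0 or fov_cols_mm <= 0:
        raise ValueError("field of view must be strictly positive")
    return PixelGeometry(fov_rows_mm / matrix_rows, fov_cols_mm / matrix_cols)


def read_image(path: str | Path) -> GrayImage:
    """Read a PNG/JPEG slice as a :class:`GrayImage`.

    RGB(A) inputs are collapsed to luminance as the equal-weight mean of the
    color channels.  The number of gray levels is inferred from the decoded
    bit depth (256 for 8-bit, 65536 for 16-bit).
    """
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
        arr = np.round(arr).astype(np.uint16 if arr.max() > 255 else np.uint8)
    if arr.dtype == np.uint8:
        levels = 256
    elif arr.dtype in (np.uint16, np.int32):
        levels = 65536
        arr = arr.astype(np.uint16)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
        levels = 256
    else:
        raise ValueError(f"unsupported pixel dtype {arr.dtype} in {path}")
    return GrayImage(arr, levels=levels)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` as PNG (8- or 16-bit by its level count).

    Float-valued mid-pipeline images are rounded to the nearest gray level.
    """
    path = Path(path)
    arr = np.round(np.asarray(img.pixels, dtype=float)).astype(
        np.uint8 if img.levels <= 256 else np.uint16
    )
    Image.fromarray(arr).save(path)


def read_roi(path: str | Path):
    """Read a polygon ROI from a two-column (x, y) vertex file.

    One vertex per line, comma/whitespace separated, optional header line.
    A final vertex identical to the first (explicit closure) is dropped.
    """
    from .roi import PolygonROI  # local import to avoid a cycle

    path = Path(path)
    verts: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            if lineno == 1 and not _is_numeric_row(parts):
                continue  # header
            if len(parts) < 2 or not _is_numeric_row(parts[:2]):
                raise ValueError(f"{path}:{lineno}: non-numeric vertex row {line!r}")
            verts.append((float(parts[0]), float(parts[1])))
    if len(verts) >= 2 and verts[-1] == verts[0]:
        verts = verts[:-1]
    if len(verts) < 3:
        raise ValueError(f"{path}: polygon needs >= 3 distinct vertices, got {len(verts)}")
    return PolygonROI(verts)


def write_roi(roi, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for x, y in roi.vertices:
            fh.write(f"{x:.6g},{y:.6g}\n")


def _is_numeric_row(parts) -> bool:
    try:
        for p in parts:
            float(p)
    except ValueError:
        return False
    return True


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement table, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table {path} missing columns: {missing}")
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    df.to_csv(path, index=False, float_format="%.6g")


_CONFIG_KEYS = {
    "clip_limit": float,
    "tile_rows": int,
    "tile_cols": int,
    "saturation_fraction": float,
    "spacing_row_mm": float,
    "spacing_col_mm": float,
    "matrix_rows": int,
    "matrix_cols": int,
    "fov_rows_mm": float,
    "fov_cols_mm": float,
    "seed": int,
}


def read_config(path: str | Path) -> dict:
    """Read a plain-text ``key = value`` configuration file.

    Recognized keys: clip_limit, tile_rows, tile_cols, saturation_fraction,
    spacing_row_mm, spacing_col_mm, matrix_rows, matrix_cols, fov_rows_mm,
    fov_cols_mm, seed.  If both direct spacings and matrix+FOV are present,
    the direct spacings win when resolved by :func:`resolve_geometry`.
    """
    cfg: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, val = line.split("=", 1)
            elif ":" in line:
                key, val = line.split(":", 1)
            else:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key = key.strip()
            if key not in _CONFIG_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            cfg[key] = _CONFIG_KEYS[key](val.strip())
    return cfg


def resolve_geometry(cfg: dict) -> PixelGeometry | None:
    """Build a :class:`PixelGeometry` from config keys, if enough are present.

    Direct spacings take precedence over matrix + FOV.
    """
    if "spacing_row_mm" in cfg and "spacing_col_mm" in cfg:
        return PixelGeometry(cfg["spacing_row_mm"], cfg["spacing_col_mm"])
    keys = ("matrix_rows", "matrix_cols", "fov_rows_mm", "fov_cols_mm")
    if all(k in cfg for k in keys):
        return geometry_from_matrix(*(cfg[k] for k in keys))
    return None
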