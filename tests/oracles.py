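"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the expected result by the most direct computation
possible (explicit loops, per-pixel scans, ANOVA by double summation) and is
kept free of any code path shared with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def otsu_brute_force(values, n_bins: int = 256):
    """Exhaustive between-class-variance scan over all bin boundaries.

    Returns (threshold, sigma_b_max) with the smallest-threshold tie-break.
    Histogram convention: value v falls in bin min(floor(v * n_bins), n_bins - 1).
    """
    values = list(values)
    hist = [0] * n_bins
    for v in values:
        b = min(int(v * n_bins), n_bins - 1)
        hist[b] += 1
    total = len(values)
    centers = [(b + 0.5) / n_bins for b in range(n_bins)]
    best_k, best_sigma = None, -1.0
    for k in range(1, n_bins):
        n0 = sum(hist[:k])
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            sigma = 0.0
        else:
            mu0 = sum(hist[b] * centers[b] for b in range(k)) / n0
            mu1 = sum(hist[b] * centers[b] for b in range(k, n_bins)) / n1
            w0, w1 = n0 / total, n1 / total
            sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma + 1e-15:
            best_sigma, best_k = sigma, k
    return best_k / n_bins, best_sigma


def clahe_brute_force(pixels, levels, tile_rows, tile_cols, clip_limit, n_bins):
    """Per-pixel CLAHE: explicit tile CDF mappings + hand-coded bilinear blend.

    Tile boundaries are the rounded equal partition; tile centers sit at the
    midpoint of each tile minus half a pixel; pixels beyond the outermost
    centers clamp to the edge mapping.
    """
    pixels = np.asarray(pixels, dtype=float)
    h, w = pixels.shape
    re = [round(i * h / tile_rows) for i in range(tile_rows + 1)]
    ce = [round(j * w / tile_cols) for j in range(tile_cols + 1)]

    def tile_lut(i, j):
        tile = pixels[re[i] : re[i + 1], ce[j] : ce[j + 1]]
        hist = [0] * n_bins
        for v in tile.ravel():
            hist[min(int(v * n_bins / levels), n_bins - 1)] += 1
        npix = tile.size
        if math.isfinite(clip_limit):
            ceiling = clip_limit * npix / n_bins
            clipped = [min(c, ceiling) for c in hist]
            excess = sum(hist) - sum(clipped)
            clipped = [c + excess / n_bins for c in clipped]
        else:
            clipped = [float(c) for c in hist]
        cdf, acc = [], 0.0
        for c in clipped:
            acc += c
            cdf.append(acc)
        return [c / acc * (levels - 1) for c in cdf]

    luts = [[tile_lut(i, j) for j in range(tile_cols)] for i in range(tile_rows)]
    ctr_r = [(re[i] + re[i + 1]) / 2.0 - 0.5 for i in range(tile_rows)]
    ctr_c = [(ce[j] + ce[j + 1]) / 2.0 - 0.5 for j in range(tile_cols)]

    def axis_blend(coord, centers):
        if len(centers) == 1:
            return 0, 0, 0.0  # (lower, upper, weight on upper)
        if coord <= centers[0]:
            return 0, 0, 0.0
        if coord >= centers[-1]:
            n = len(centers) - 1
            return n, n, 0.0
        for i in range(1, len(centers)):
            if coord <= centers[i]:
                wt = (coord - centers[i - 1]) / (centers[i] - centers[i - 1])
                return i - 1, i, wt
        raise AssertionError

    out = np.empty_like(pixels)
    for r in range(h):
        i0, i1, wr = axis_blend(r, ctr_r)
        for c in range(w):
            j0, j1, wc = axis_blend(c, ctr_c)
            b = min(int(pixels[r, c] * n_bins / levels), n_bins - 1)
            out[r, c] = (
                (1 - wr) * (1 - wc) * luts[i0][j0][b]
                + (1 - wr) * wc * luts[i0][j1][b]
                + wr * (1 - wc) * luts[i1][j0][b]
                + wr * wc * luts[i1][j1][b]
            )
    return out


def global_hist_eq(pixels, levels, n_bins):
    """Plain global histogram equalization by direct CDF rescaling."""
    pixels = np.asarray(pixels, dtype=float)
    hist = [0] * n_bins
    for v in pixels.ravel():
        hist[min(int(v * n_bins / levels), n_bins - 1)] += 1
    cdf, acc = [], 0.0
    for c in hist:
        acc += c
        cdf.append(acc)
    lut = [c / acc * (levels - 1) for c in cdf]
    out = np.empty_like(pixels)
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            out[r, c] = lut[min(int(pixels[r, c] * n_bins / levels), n_bins - 1)]
    return out


def point_in_polygon(px, py, vertices):
    """Even-odd crossing test for one point, half-open edge rule."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if y1 == y2:
            continue
        ylo, yhi = (y1, y2) if y1 < y2 else (y2, y1)
        if ylo <= py < yhi:
            xi = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xi:
                inside = not inside
    return inside


def rasterize_brute_force(vertices, height, width):
    mask = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            mask[r, c] = point_in_polygon(float(c), float(r), vertices)
    return mask


def icc_2_1_brute_force(matrix):
    """ICC(2,1) by explicit double-loop ANOVA summation."""
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
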