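"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: dilation and convolution by explicit
shift-and-accumulate loops over structuring-element / kernel offsets, max
pooling by explicit block loops, and greedy matching by enumerating every
candidate pair in pure Python.  None of it shares code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_dilate(grid: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel max over a disk of offsets, via shifted copies."""
    h, w = grid.shape
    out = np.zeros_like(grid)
    for a in range(-radius, radius + 1):
        for b in range(-radius, radius + 1):
            if a * a + b * b > radius * radius:
                continue
            shifted = np.zeros_like(grid)
            src_r = slice(max(0, a), min(h, h + a))
            dst_r = slice(max(0, -a), min(h, h - a))
            src_c = slice(max(0, b), min(w, w + b))
            dst_c = slice(max(0, -b), min(w, w - b))
            shifted[dst_r, dst_c] = grid[src_r, src_c]
            out = np.maximum(out, shifted)
    return out


def brute_gaussian_convolve(grid: np.ndarray, sigma: float) -> np.ndarray:
    """Zero-padded convolution with the normalized Gaussian truncated at 4*sigma."""
    radius = int(math.ceil(4.0 * sigma))
    weights = {}
    total = 0.0
    for a in range(-radius, radius + 1):
        for b in range(-radius, radius + 1):
            wgt = math.exp(-(a * a + b * b) / (2.0 * sigma * sigma))
            weights[(a, b)] = wgt
            total += wgt
    h, w = grid.shape
    out = np.zeros_like(grid, dtype=np.float64)
    for (a, b), wgt in weights.items():
        shifted = np.zeros_like(grid, dtype=np.float64)
        src_r = slice(max(0, a), min(h, h + a))
        dst_r = slice(max(0, -a), min(h, h - a))
        src_c = slice(max(0, b), min(w, w + b))
        dst_c = slice(max(0, -b), min(w, w - b))
        shifted[dst_r, dst_c] = grid[src_r, src_c]
        out += (wgt / total) * shifted
    return out


def brute_single_point_peak(radius: int, sigma: float) -> float:
    """Peak response of an isolated dilated-and-smoothed single point."""
    r_total = radius + int(math.ceil(4.0 * sigma)) + 1
    size = 2 * r_total + 1
    grid = np.zeros((size, size))
    grid[r_total, r_total] = 1.0
    smoothed = brute_gaussian_convolve(brute_dilate(grid, radius), sigma)
    return float(smoothed[r_total, r_total])


def brute_label(points, shape, radius: int, sigma: float) -> np.ndarray:
    """Full naive label pipeline: rasterize, dilate, smooth, peak-normalize, clip."""
    h, w = shape
    grid = np.zeros((h, w))
    for x, y in points:
        grid[int(math.ceil(y - 0.5)), int(math.ceil(x - 0.5))] = 1.0
    smoothed = brute_gaussian_convolve(brute_dilate(grid, radius), sigma)
    smoothed /= brute_single_point_peak(radius, sigma)
    return np.clip(smoothed, 0.0, 1.0)


def brute_max_pool(grid: np.ndarray, k: int) -> np.ndarray:
    h, w = grid.shape
    out = np.zeros((h // k, w // k))
    for i in range(h // k):
        for j in range(w // k):
            out[i, j] = grid[i * k : (i + 1) * k, j * k : (j + 1) * k].max()
    return out


def brute_greedy_match(gt, pred, threshold: float):
    """Distance-ascending greedy one-to-one matching, pure Python."""
    candidates = []
    for gi, (gx, gy) in enumerate(gt):
        for pi, (px, py) in enumerate(pred):
            d = math.hypot(gx - px, gy - py)
            if d <= threshold:
                candidates.append((d, gi, pi))
    candidates.sort()
    used_g, used_p = set(), set()
    pairs = []
    for d, gi, pi in candidates:
        if gi not in used_g and pi not in used_p:
            pairs.append((gi, pi, d))
            used_g.add(gi)
            used_p.add(pi)
    return pairs
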