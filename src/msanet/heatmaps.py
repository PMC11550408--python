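"""Heatmap label construction: rasterize points, dilate, smooth, downsample.

Sparse seed-centroid annotations are turned into continuous regression
targets in three steps: each point becomes a single 1-valued pixel; a
morphological dilation with a disk structuring element grows it to roughly
seed size; a normalized Gaussian filter diffuses the dilated disks into a
smooth probability landscape.  The smoothed map is rescaled so that an
isolated seed center sits at exactly 1.0 (the peak response of a single
isolated point with the same disk radius and sigma is used as the
reference), then clipped to [0, 1].

Multi-scale supervision targets are produced by non-overlapping max pooling
of the full-resolution label at 1/4, 1/8, 1/16, and 1/32 of the input
resolution.  Max pooling preserves the global maximum, and because only the
foreground plant carries labels, the coarsest maps cover the whole plant and
act as attention supervision.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import ndimage

from msanet.errors import ValidationError

#: Scale divisors of the multi-scale label stack: full resolution plus the
#: four encoder stage resolutions.
SCALE_DIVISORS: tuple[int, ...] = (1, 4, 8, 16, 32)

#: Default label parameters for ~2000-px plant crops; scaled fixtures use
#: radius 3 / sigma 1.5.
DEFAULT_DILATION_RADIUS = 8
DEFAULT_SIGMA = 3.0


@dataclass
class HeatmapLabel:
    """Full-resolution continuous label in [0, 1] with its construction params."""

    values: np.ndarray
    dilation_radius: int
    sigma: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MultiScaleLabels:
    """One grid per scale divisor; ``maps[1]`` is the full-resolution label."""

    maps: dict[int, np.ndarray]

    @property
    def divisors(self) -> tuple[int, ...]:
        return tuple(sorted(self.maps))


def points_to_binary(
    points: list[tuple[float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize points into a binary grid with a 1 at each point's pixel.

    Sub-pixel coordinates are rounded to the nearest pixel with exact .5
    fractions rounding toward the zero origin, so the rounded index never
    exceeds the in-bounds coordinate range.  Points that round onto the same
    pixel merge into one foreground pixel.
    """
    h, w = shape
    grid = np.zeros((h, w), dtype=np.float64)
    for i, (x, y) in enumerate(points):
        if not (0.0 <= x < w and 0.0 <= y < h):
            raise ValidationError(
                f"point {i} at ({x}, {y}) outside grid bounds [0, {w}) x [0, {h})"
            )
        col = int(np.ceil(x - 0.5))
        row = int(np.ceil(y - 0.5))
        grid[row, col] = 1.0
    return grid


@lru_cache(maxsize=64)
def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk: offsets (a, b) with a^2 + b^2 <= radius^2."""
    if radius < 0:
        raise ValidationError(f"dilation radius must be >= 0, got {radius}")
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def dilate(binary: np.ndarray, radius: int) -> np.ndarray:
    """Grey dilation with a disk structuring element; radius 0 is the identity."""
    if radius < 0:
        raise ValidationError(f"dilation radius must be >= 0, got {radius}")
    if radius == 0:
        return np.array(binary, dtype=np.float64, copy=True)
    return ndimage.grey_dilation(
        np.asarray(binary, dtype=np.float64),
        footprint=disk_footprint(radius),
        mode="constant",
        cval=0.0,
    )


@lru_cache(maxsize=64)
def gaussian_kernel(sigma: float) -> np.ndarray:
    """2-D isotropic Gaussian kernel, truncated at 4*sigma, normalized to sum 1."""
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    r = int(np.ceil(4.0 * sigma))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    kernel = np.exp(-(xx * xx + yy * yy) / (2.0 * sigma * sigma))
    return kernel / kernel.sum()


@lru_cache(maxsize=64)
def _isolated_peak_response(radius: int, sigma: float) -> float:
    """Peak of (single-point disk) * G — the normalization reference."""
    r_total = int(radius + np.ceil(4.0 * sigma)) + 1
    size = 2 * r_total + 1
    single = np.zeros((size, size))
    single[r_total, r_total] = 1.0
    smoothed = ndimage.convolve(
        dilate(single, radius), gaussian_kernel(sigma), mode="constant", cval=0.0
    )
    return float(smoothed[r_total, r_total])


def gaussian_smooth_and_normalize(
    dilated: np.ndarray, sigma: float, dilation_radius: int
) -> HeatmapLabel:
    """Convolve a dilated point map with a Gaussian and peak-normalize.

    Division by the isolated single-point reference response makes isolated
    seed centers exactly 1.0; overlapping responses are clipped back to 1.
    """
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    dilated = np.asarray(dilated, dtype=np.float64)
    smoothed = ndimage.convolve(dilated, gaussian_kernel(sigma), mode="constant", cval=0.0)
    smoothed /= _isolated_peak_response(dilation_radius, float(sigma))
    np.clip(smoothed, 0.0, 1.0, out=smoothed)
    return HeatmapLabel(values=smoothed, dilation_radius=dilation_radius, sigma=float(sigma))


def make_label(
    points: list[tuple[float, float]],
    shape: tuple[int, int],
    dilation_radius: int = DEFAULT_DILATION_RADIUS,
    sigma: float = DEFAULT_SIGMA,
) -> HeatmapLabel:
    """Point set -> binary raster -> disk dilation -> normalized Gaussian label."""
    binary = points_to_binary(points, shape)
    return gaussian_smooth_and_normalize(dilate(binary, dilation_radius), sigma, dilation_radius)


def pad_to_multiple(
    arr: np.ndarray, multiple: int = 32, mode: str = "constant"
) -> tuple[np.ndarray, tuple[int, int]]:
    """Pad the trailing edge of the first two axes up to a multiple.

    Returns the padded array and the (pad_h, pad_w) added, so downstream
    outputs can be cropped back.  Images use ``mode='reflect'``; labels use
    zero padding so the padding carries no supervision signal.
    """
    h, w = arr.shape[:2]
    pad_h = (-h) % multiple
    pad_w = (-w) % multiple
    if pad_h == 0 and pad_w == 0:
        return arr, (0, 0)
    pad_spec = [(0, pad_h), (0, pad_w)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, pad_spec, mode=mode), (pad_h, pad_w)


def max_pool(arr: np.ndarray, k: int) -> np.ndarray:
    """Non-overlapping k x k max pooling of an exactly divisible 2-D grid."""
    h, w = arr.shape
    if h % k or w % k:
        raise ValidationError(f"grid {h}x{w} not divisible by pooling factor {k}")
    return arr.reshape(h // k, k, w // k, k).max(axis=(1, 3))


def downsample_labels(
    label: HeatmapLabel | np.ndarray, divisors: tuple[int, ...] = SCALE_DIVISORS
) -> MultiScaleLabels:
    """Max-pool the full-resolution label to each scale in the stack.

    The label must already be padded to a multiple of 32 (the deepest stage
    stride); callers pad with :func:`pad_to_multiple` first.
    """
    values = label.values if isinstance(label, HeatmapLabel) else np.asarray(label)
    h, w = values.shape
    if h % 32 or w % 32:
        raise ValidationError(
            f"label shape {h}x{w} is not a multiple of 32; pad with pad_to_multiple first"
        )
    maps = {k: (values if k == 1 else max_pool(values, k)) for k in divisors}
    return MultiScaleLabels(maps=maps)


def save_heatmap(values: np.ndarray, path: str | Path) -> Path:
    """Persist a heatmap losslessly (32-bit float TIFF or .npy by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    else:
        np.save(path, np.asarray(values, dtype=np.float32))
    return path


def save_preview_png(values: np.ndarray, path: str | Path) -> Path:
    """8-bit PNG preview of a [0, 1] heatmap for visual checks."""
    from PIL import Image

    arr = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(Path(path))
    return Path(path)
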