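"""Predicted-heatmap readout: padding-aware forward pass and peak extraction.

The readout operator is thresholded local-maximum detection with greedy
minimum-distance suppression: connected plateaus of equal-valued local
maxima contribute their centroid once, candidates with value >= tau are
visited in descending value (ties broken by row, then column), and a
candidate is kept only if it lies at least ``min_distance`` pixels from
every already-kept point.  Because isolated seed centers are trained toward
1.0, any moderate threshold separates seeds from background response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima

from msanet.errors import ValidationError
from msanet.heatmaps import pad_to_multiple
from msanet.model import MSANet


@dataclass
class PeakConfig:
    threshold: float = 0.4
    min_distance: float = 8.0  # default matches the default label dilation radius
    border_margin: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.min_distance < 1:
            raise ValidationError(f"min_distance must be >= 1, got {self.min_distance}")


def predict_heatmap(model: MSANet, image: np.ndarray) -> np.ndarray:
    """Full-resolution predicted map in [0, 1], same H x W as the input image.

    The image is reflect-padded to a multiple of 32 internally and the
    output cropped back, so arbitrary sizes are accepted.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError(f"expected an RGB (H, W, 3) image, got shape {img.shape}")
    if img.max() > 1.0:
        img = img / 255.0
    h, w = img.shape[:2]
    padded, _ = pad_to_multiple(img, 32, mode="reflect")
    pred = model.predict(padded)
    return pred.full_map[:h, :w]


def extract_points(heatmap: np.ndarray, cfg: PeakConfig = PeakConfig()) -> list[tuple[float, float]]:
    """Extract seed coordinates (x, y) from a [0, 1] heatmap.

    Returns plateau centroids of local maxima with value >= threshold,
    greedily suppressed to pairwise separation >= min_distance in descending
    value order.
    """
    hm = np.asarray(heatmap, dtype=np.float64)
    if hm.size == 0 or hm.max() <= 0:
        return []

    maxima = local_maxima(hm, connectivity=2, allow_borders=True)
    labeled, n_regions = ndimage.label(maxima, structure=np.ones((3, 3), dtype=int))
    if n_regions == 0:
        return []
    centroids = ndimage.center_of_mass(maxima, labeled, range(1, n_regions + 1))
    # plateau value: heatmap is constant over the region; read it at one pixel
    first_pix = ndimage.find_objects(labeled)
    h, w = hm.shape
    candidates: list[tuple[float, float, float]] = []  # (value, row, col)
    for region_idx, (cy, cx) in enumerate(centroids):
        sl = first_pix[region_idx]
        region_mask = labeled[sl] == region_idx + 1
        value = float(hm[sl][region_mask][0])
        if value < cfg.threshold:
            continue
        m = cfg.border_margin
        if m and not (m <= cy < h - m and m <= cx < w - m):
            continue
        candidates.append((value, float(cy), float(cx)))

    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[tuple[float, float]] = []  # (x, y)
    min_d2 = cfg.min_distance**2
    for value, cy, cx in candidates:
        if all((cx - kx) ** 2 + (cy - ky) ** 2 >= min_d2 for kx, ky in kept):
            kept.append((cx, cy))
    return kept
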