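"""Vertical seed-distribution traits: KDE profiles, genotype averages, KL divergence.

The trait summarizes a plant's shoot architecture by the distribution of its
seeds' vertical (y-axis) image positions.  Per plant, a Gaussian kernel
density estimate

    f(x) = (1/n) sum_i (1/h) K((x - x_i) / h)

is evaluated on an explicit grid, with the bandwidth h chosen by Scott's
rule, h = sd(x) * n^(-1/5) (unbiased sample standard deviation).  For
cross-genotype comparison, each plant's seed-y extent is first mapped
linearly onto a normalized 0-1000 axis, per-plant profiles are averaged
pointwise on a shared grid, and the average is rescaled to integrate to 1.
Discrepancy between two profiles is measured by the (asymmetric)
Kullback-Leibler divergence  D(P||Q) = \\int p log(p/q) dx, computed by
trapezoid quadrature with the reference density floored at 1e-12.

Image y increases downward, matching pixel coordinates; plots can flip the
axis but the trait itself works in image coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from msanet.errors import ValidationError

PIXEL_UNITS = "pixels"
NORMALIZED_UNITS = "normalized_0_1000"

DEFAULT_GRID_SIZE = 512
DENSITY_FLOOR = 1e-12


@dataclass
class KDEProfile:
    """A density curve on an explicit grid with its bandwidth and units."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int
    units: str = PIXEL_UNITS

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def mode(self) -> float:
        """Grid position of the density peak."""
        return float(self.grid[int(np.argmax(self.density))])


def scott_bandwidth(samples: Sequence[float]) -> float:
    """Scott's rule: h = sd * n^(-1/5), with the unbiased sample sd."""
    arr = np.asarray(samples, dtype=np.float64)
    if arr.size < 2:
        raise ValidationError(
            f"Scott's rule needs n >= 2 samples (got {arr.size}); pass an explicit bandwidth"
        )
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise ValidationError(
            "Scott's rule is undefined for zero-variance samples; pass an explicit bandwidth"
        )
    return sd * arr.size ** (-1.0 / 5.0)


def kde(samples: Sequence[float], h: float, grid: np.ndarray, units: str = PIXEL_UNITS) -> KDEProfile:
    """Gaussian-kernel density estimate evaluated on ``grid``."""
    arr = np.asarray(samples, dtype=np.float64)
    if arr.size == 0:
        raise ValidationError("kde requires at least one sample")
    if h <= 0:
        raise ValidationError(f"bandwidth must be > 0, got {h}")
    grid = np.asarray(grid, dtype=np.float64)
    density = norm.pdf(grid[None, :], loc=arr[:, None], scale=h).mean(axis=0)
    return KDEProfile(grid=grid, density=density, bandwidth=float(h), n=int(arr.size), units=units)


def _default_grid(lo: float, hi: float, h: float, grid_size: int) -> np.ndarray:
    return np.linspace(lo - 4.0 * h, hi + 4.0 * h, grid_size)


def vertical_profile(
    points: Sequence[tuple[float, float]],
    image_height: float,
    normalize: bool = False,
    bandwidth: Optional[float] = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> KDEProfile:
    """KDE profile of seed y-positions for one plant.

    With ``normalize`` set, y values are mapped linearly so the plant's own
    seed extent (min y to max y) spans 0-1000 before the KDE; the convention
    is recorded in ``units``.
    """
    ys = np.asarray([y for _, y in points], dtype=np.float64)
    if ys.size < 2 and bandwidth is None:
        raise ValidationError(
            f"need >= 2 points for Scott's rule (got {ys.size}); pass an explicit bandwidth"
        )
    units = PIXEL_UNITS
    if normalize:
        span = ys.max() - ys.min()
        if span == 0.0:
            raise ValidationError("cannot normalize: all seed y-positions are identical")
        ys = (ys - ys.min()) / span * 1000.0
        units = NORMALIZED_UNITS
    h = bandwidth if bandwidth is not None else scott_bandwidth(ys)
    grid = _default_grid(float(ys.min()), float(ys.max()), h, grid_size)
    return kde(ys, h, grid, units=units)


def genotype_average_profile(profiles: Sequence[KDEProfile]) -> KDEProfile:
    """Pointwise average of normalized per-plant profiles, rescaled to integral 1."""
    if not profiles:
        raise ValidationError("genotype_average_profile requires at least one profile")
    units = {p.units for p in profiles}
    if units != {NORMALIZED_UNITS}:
        raise ValidationError(
            f"all profiles must be in {NORMALIZED_UNITS!r} units, got {sorted(units)}"
        )
    lo = min(float(p.grid.min()) for p in profiles)
    hi = max(float(p.grid.max()) for p in profiles)
    grid_size = max(len(p.grid) for p in profiles)
    grid = np.linspace(lo, hi, grid_size)
    stacked = np.stack(
        [np.interp(grid, p.grid, p.density, left=0.0, right=0.0) for p in profiles]
    )
    mean_density = stacked.mean(axis=0)
    integral = np.trapezoid(mean_density, grid)
    if integral <= 0:
        raise ValidationError("average profile has zero mass; cannot renormalize")
    return KDEProfile(
        grid=grid,
        density=mean_density / integral,
        bandwidth=float(np.mean([p.bandwidth for p in profiles])),
        n=int(sum(p.n for p in profiles)),
        units=NORMALIZED_UNITS,
    )


def kl_divergence(p: KDEProfile, q: KDEProfile) -> float:
    """Trapezoid approximation of D(P||Q) = \\int p log(p / q) dx, clamped at 0.

    Both profiles are interpolated onto a shared grid covering both supports
    (each already padded by 4h on construction); q is floored at 1e-12 so
    the integrand stays finite where q vanishes.
    """
    if p.units != q.units:
        raise ValidationError(f"unit mismatch: {p.units!r} vs {q.units!r}")
    lo = min(float(p.grid.min()), float(q.grid.min()))
    hi = max(float(p.grid.max()), float(q.grid.max()))
    grid = np.linspace(lo, hi, max(len(p.grid), len(q.grid)))
    pd = np.interp(grid, p.grid, p.density, left=0.0, right=0.0)
    qd = np.maximum(np.interp(grid, q.grid, q.density, left=0.0, right=0.0), DENSITY_FLOOR)
    integrand = np.where(pd > 0.0, pd * np.log(np.maximum(pd, DENSITY_FLOOR) / qd), 0.0)
    value = float(np.trapezoid(integrand, grid))
    if value < -1e-9:
        raise ValidationError(f"KL divergence evaluated to {value}; profiles are inconsistent")
    return max(value, 0.0)


def profile_to_csv(profile: KDEProfile, path: str | Path) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame({"grid": profile.grid, "density": profile.density}).to_csv(path, index=False)
    return path
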