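"""Synthetic plant-image fixtures with known seed-point ground truth.

Real inputs are RGB crops of single mature plants with every seed centroid
point-annotated; background soil, stems, and neighboring-plant material are
unannotated clutter.  The simulator emulates the parts of that setting the
pipeline is sensitive to:

* seed-like elliptical blobs whose centroids are the annotated points, with
  vertical (y) positions drawn from a per-genotype mixture of truncated
  normals — the quantity the vertical-distribution trait must recover;
* a stem polyline so seeds sit along a plant-like structure;
* unannotated distractor blobs sharing the seed size range but drawn from a
  different hue distribution, mimicking the dominant false-positive mode
  (soil mistaken for a seed): an untrained model confuses them, a trained
  model can separate them by color;
* textured background noise.

Everything is deterministic given ``rng_seed``: sampling, rendering, and the
files written by :func:`generate_dataset` (images, Labelme JSON, CSV, and a
YAML manifest sufficient to regenerate the fixtures byte-identically).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from PIL import Image
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from msanet.annotations import PointAnnotation, write_labelme_points, write_points_csv
from msanet.errors import CapacityError, ValidationError

# Color palette (RGB). Seeds are warm tan; distractors are cool gray-blue of
# the same size class; background is a noisy soil/foliage green-brown.
SEED_COLOR = np.array([205.0, 175.0, 115.0])
DISTRACTOR_COLOR = np.array([185.0, 162.0, 130.0])
BACKGROUND_COLOR = np.array([95.0, 115.0, 70.0])
STEM_COLOR = np.array([70.0, 52.0, 35.0])

MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass
class PlantSimConfig:
    """Study conditions for one simulated genotype."""

    image_size: tuple[int, int] = (128, 128)  # (height, width)
    n_seeds: int = 30
    n_seeds_range: Optional[tuple[int, int]] = None  # per-plant uniform draw
    seed_radius_range: tuple[float, float] = (2.0, 3.5)
    vertical_mixture: Sequence[tuple[float, float, float]] = (
        (1.0, 0.5, 0.18),
    )  # (weight, mean_fraction of height, sd_fraction)
    horizontal_sd_fraction: float = 0.16
    n_distractors: int = 12
    min_separation: float = 9.0
    noise_amplitude: float = 18.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValidationError(f"image_size too small: {self.image_size}")
        if self.n_seeds < 0 or self.n_distractors < 0:
            raise ValidationError("n_seeds and n_distractors must be >= 0")
        if self.n_seeds_range is not None:
            lo, hi = self.n_seeds_range
            if not (0 <= lo <= hi):
                raise ValidationError(f"invalid n_seeds_range {self.n_seeds_range}")
        if self.min_separation < 1:
            raise ValidationError("min_separation must be >= 1 pixel")
        if not self.seed_radius_range[0] <= self.seed_radius_range[1]:
            raise ValidationError("seed_radius_range must be (min, max) with min <= max")
        weights = [wt for wt, _, _ in self.vertical_mixture]
        if not weights or any(wt <= 0 for wt in weights):
            raise ValidationError("mixture weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError(f"mixture weights must sum to 1, got {sum(weights)}")
        for _, mean_frac, sd_frac in self.vertical_mixture:
            if not 0.0 <= mean_frac <= 1.0:
                raise ValidationError(f"mean_fraction {mean_frac} outside [0, 1]")
            if sd_frac <= 0:
                raise ValidationError(f"sd_fraction must be > 0, got {sd_frac}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal; falls back to clipping after 1000 draws."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_seed_points(
    cfg: PlantSimConfig,
    rng: Optional[np.random.Generator] = None,
    n_seeds: Optional[int] = None,
) -> list[tuple[float, float]]:
    """Sample seed centroids: y from the vertical mixture, x around the stem.

    Pairwise distances respect ``cfg.min_separation`` via rejection sampling
    with a hard attempt budget; exceeding it raises :class:`CapacityError`.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_seeds if n_seeds is None else n_seeds
    h, w = cfg.image_size
    weights = np.array([wt for wt, _, _ in cfg.vertical_mixture])
    points: list[tuple[float, float]] = []
    attempts = 0
    while len(points) < n:
        attempts += 1
        if attempts > MAX_PLACEMENT_ATTEMPTS:
            raise CapacityError(
                f"placed only {len(points)}/{n} seeds in {MAX_PLACEMENT_ATTEMPTS} attempts; "
                "reduce n_seeds or min_separation"
            )
        comp = int(rng.choice(len(weights), p=weights))
        _, mean_frac, sd_frac = cfg.vertical_mixture[comp]
        y = _truncated_normal(rng, mean_frac * h, sd_frac * h, 0.0, h - 1.0)
        x = _truncated_normal(rng, w / 2.0, cfg.horizontal_sd_fraction * w, 0.0, w - 1.0)
        if all(
            (x - px) ** 2 + (y - py) ** 2 >= cfg.min_separation**2 for px, py in points
        ):
            points.append((x, y))
    return points


def _paint_blob(
    img: np.ndarray,
    cx: float,
    cy: float,
    radius: float,
    color: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Draw a slightly eccentric, slightly rotated ellipse centered at (cx, cy)."""
    h, w = img.shape[:2]
    ratio = rng.uniform(0.75, 1.0)
    angle = rng.uniform(0.0, np.pi)
    jitter = rng.normal(0.0, 6.0, size=3)
    rr, cc = draw_ellipse(cy, cx, radius, radius * ratio, shape=(h, w), rotation=angle)
    img[rr, cc] = np.clip(color + jitter, 0.0, 255.0)


def render_plant_image(
    points: Sequence[tuple[float, float]],
    cfg: PlantSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render an RGB uint8 image: background, stem, distractors, then seeds.

    Seeds are painted last so every annotated centroid lies on a seed blob;
    distractor centers keep their distance from annotated points so no
    distractor is accidentally annotated.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.rng_seed, 1])
    h, w = cfg.image_size
    r_lo, r_hi = cfg.seed_radius_range

    img = np.clip(
        BACKGROUND_COLOR[None, None, :]
        + rng.uniform(-cfg.noise_amplitude, cfg.noise_amplitude, size=(h, w, 3)),
        0.0,
        255.0,
    )

    # Stem: piecewise-linear path from the bottom center to the top, 2 px wide.
    n_knots = 6
    knot_y = np.linspace(h - 1, 0, n_knots).astype(int)
    knot_x = np.clip(
        (w / 2.0 + rng.normal(0.0, 0.03 * w, size=n_knots)).astype(int), 1, w - 2
    )
    for (y0, x0), (y1, x1) in zip(zip(knot_y, knot_x), zip(knot_y[1:], knot_x[1:])):
        for dx in (-1, 0, 1):
            rr, cc = draw_line(y0, np.clip(x0 + dx, 0, w - 1), y1, np.clip(x1 + dx, 0, w - 1))
            img[rr, cc] = STEM_COLOR

    # Distractors: soil-like blobs of the seed size class with a slightly
    # shifted hue, lying in the soil bands beside the plant.  Locally they
    # are easy to confuse with seeds; their off-plant position is the
    # reliable cue, so separating them rewards multi-scale context.
    placed = 0
    guard = 0
    keepout = r_hi + cfg.seed_radius_range[1] + 2.0
    while placed < cfg.n_distractors and guard < MAX_PLACEMENT_ATTEMPTS:
        guard += 1
        band = rng.uniform(0.0, 0.25 * (w - 1))
        dx = band if rng.random() < 0.5 else (w - 1) - band
        dy = rng.uniform(0, h - 1)
        radius = rng.uniform(r_lo, r_hi)
        if any((dx - px) ** 2 + (dy - py) ** 2 < keepout**2 for px, py in points):
            continue
        _paint_blob(img, dx, dy, radius, DISTRACTOR_COLOR, rng)
        placed += 1

    for x, y in points:
        _paint_blob(img, x, y, rng.uniform(r_lo, r_hi), SEED_COLOR, rng)

    return img.astype(np.uint8)


def _plant_seed(base_seed: int, genotype_index: int, plant_index: int) -> int:
    """Stable per-plant RNG seed below 2**31."""
    return (base_seed * 1_000_003 + genotype_index * 10_007 + plant_index * 101 + 17) % (2**31)


def simulate_plant(
    cfg: PlantSimConfig, plant_seed: int
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Sample one plant's points and image from a single per-plant seed."""
    rng = np.random.default_rng(plant_seed)
    n = cfg.n_seeds
    if cfg.n_seeds_range is not None:
        lo, hi = cfg.n_seeds_range
        n = int(rng.integers(lo, hi + 1))
    points = sample_seed_points(cfg, rng=rng, n_seeds=n)
    image = render_plant_image(points, cfg, rng=rng)
    return image, points


def generate_dataset(
    n_plants: int,
    cfg_per_genotype: Mapping[str, PlantSimConfig],
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict:
    """Write ``n_plants`` images per genotype plus annotations and a manifest.

    Layout: ``<out_dir>/<plant_id>.png``, ``<plant_id>.json`` (Labelme),
    ``<plant_id>.csv``, and ``manifest.yaml`` recording every config and the
    derived per-plant seeds, so the fixture set can be regenerated
    byte-identically from the manifest alone.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise ValidationError(
            f"output directory {out_dir} is not empty; pass overwrite=True to replace"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"n_plants": int(n_plants), "genotypes": {}, "plants": []}
    for gi, (genotype, cfg) in enumerate(sorted(cfg_per_genotype.items())):
        gcfg = asdict(cfg)
        gcfg["vertical_mixture"] = [list(c) for c in cfg.vertical_mixture]
        manifest["genotypes"][genotype] = gcfg
        for pi in range(n_plants):
            plant_id = f"{genotype}_plant{pi:03d}"
            plant_seed = _plant_seed(cfg.rng_seed, gi, pi)
            image, points = simulate_plant(cfg, plant_seed)
            h, w = cfg.image_size
            img_path = out_dir / f"{plant_id}.png"
            Image.fromarray(image).save(img_path)
            ann = PointAnnotation(
                plant_id=plant_id,
                points=list(points),
                width=w,
                height=h,
                genotype=genotype,
                image_path=img_path,
            )
            write_labelme_points(ann, out_dir / f"{plant_id}.json")
            write_points_csv(ann, out_dir / f"{plant_id}.csv")
            manifest["plants"].append(
                {
                    "plant_id": plant_id,
                    "genotype": genotype,
                    "plant_seed": plant_seed,
                    "n_seeds": len(points),
                }
            )
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def regenerate_from_manifest(manifest_path: str | Path, out_dir: str | Path, overwrite: bool = False) -> dict:
    """Re-run :func:`generate_dataset` from a saved manifest."""
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    cfgs = {}
    for genotype, gcfg in manifest["genotypes"].items():
        gcfg = dict(gcfg)
        gcfg["image_size"] = tuple(gcfg["image_size"])
        gcfg["seed_radius_range"] = tuple(gcfg["seed_radius_range"])
        if gcfg.get("n_seeds_range") is not None:
            gcfg["n_seeds_range"] = tuple(gcfg["n_seeds_range"])
        gcfg["vertical_mixture"] = [tuple(c) for c in gcfg["vertical_mixture"]]
        cfgs[genotype] = PlantSimConfig(**gcfg)
    return generate_dataset(manifest["n_plants"], cfgs, out_dir, overwrite=overwrite)
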