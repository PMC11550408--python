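"""Point-annotation I/O: Labelme JSON, CSV point lists, and metric reports.

Coordinate convention throughout the package: 0-based pixels, ``x`` is the
column index increasing rightward, ``y`` the row index increasing downward.
Sub-pixel coordinates are preserved exactly; a point is in-bounds when
``0 <= x < width`` and ``0 <= y < height`` (half-open ranges).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from msanet.errors import ValidationError

logger = logging.getLogger(__name__)

#: Metric names accepted by :func:`write_metrics_report`.
KNOWN_METRICS = frozenset(
    {"R2", "MAE", "RMSE", "MED", "precision", "recall", "F1", "TP", "FP", "FN"}
)


@dataclass
class PointAnnotation:
    """Seed-centroid point annotations for one plant image.

    ``width``/``height`` may be ``None`` for annotations read from bare CSV
    point lists, in which case bounds checking is skipped.
    """

    plant_id: str
    points: list[tuple[float, float]] = field(default_factory=list)
    width: Optional[int] = None
    height: Optional[int] = None
    genotype: Optional[str] = None
    image_path: Optional[Path] = None

    def __post_init__(self) -> None:
        self.points = [(float(x), float(y)) for x, y in self.points]
        if self.width is not None and self.height is not None:
            if self.width < 1 or self.height < 1:
                raise ValidationError(
                    f"image dimensions must be >= 1, got {self.width}x{self.height}"
                )
            self.validate_bounds()
        seen: set[tuple[float, float]] = set()
        dupes = [i for i, p in enumerate(self.points) if p in seen or seen.add(p)]
        if dupes:
            logger.warning(
                "annotation %s contains %d duplicate point(s) at indices %s "
                "(kept; duplicates bias counts if dropped silently)",
                self.plant_id,
                len(dupes),
                dupes,
            )

    def validate_bounds(self) -> None:
        for i, (x, y) in enumerate(self.points):
            if not (0.0 <= x < self.width and 0.0 <= y < self.height):
                raise ValidationError(
                    f"point {i} at ({x}, {y}) outside the half-open image bounds "
                    f"[0, {self.width}) x [0, {self.height})"
                )

    @property
    def n_points(self) -> int:
        return len(self.points)


def read_labelme_points(path: str | Path) -> PointAnnotation:
    """Read a Labelme-style JSON file, keeping only ``point`` shapes.

    Non-point shapes (polygons, rectangles, ...) are skipped with a logged
    warning.  Point order follows the file.  Raises :class:`ValidationError`
    if any point lies outside the recorded image dimensions.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise OSError(f"cannot read Labelme file {path}: {exc}") from exc

    try:
        width = int(doc["imageWidth"])
        height = int(doc["imageHeight"])
        shapes = doc["shapes"]
    except KeyError as exc:
        raise ValidationError(f"{path}: missing required Labelme key {exc}") from exc

    points: list[tuple[float, float]] = []
    for shape in shapes:
        if shape.get("shape_type") != "point":
            logger.warning(
                "%s: ignoring non-point shape of type %r", path, shape.get("shape_type")
            )
            continue
        (x, y), *rest = shape["points"]
        if rest:
            logger.warning("%s: point shape with extra vertices; using the first", path)
        points.append((float(x), float(y)))

    meta = doc.get("msanetMeta", {})
    return PointAnnotation(
        plant_id=meta.get("plant_id", path.stem),
        points=points,
        width=width,
        height=height,
        genotype=meta.get("genotype"),
        image_path=path.parent / doc["imagePath"] if doc.get("imagePath") else None,
    )


def write_labelme_points(ann: PointAnnotation, path: str | Path) -> Path:
    """Write an annotation as Labelme-style JSON with ``point`` shapes."""
    path = Path(path)
    doc = {
        "version": "5.0.0",
        "flags": {},
        "shapes": [
            {
                "label": "seed",
                "points": [[x, y]],
                "group_id": None,
                "shape_type": "point",
                "flags": {},
            }
            for x, y in ann.points
        ],
        "imagePath": ann.image_path.name if ann.image_path else "",
        "imageData": None,
        "imageHeight": ann.height,
        "imageWidth": ann.width,
        "msanetMeta": {"plant_id": ann.plant_id, "genotype": ann.genotype},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path


CSV_COLUMNS = ["plant_id", "genotype", "x", "y"]


def write_points_csv(ann: PointAnnotation, path: str | Path) -> Path:
    """Write points as CSV with header ``plant_id,genotype,x,y``.

    Coordinates are written with Python's shortest round-tripping float
    representation, so ``read_points_csv(write_points_csv(a))`` reproduces
    them exactly.
    """
    path = Path(path)
    frame = pd.DataFrame(
        {
            "plant_id": [ann.plant_id] * ann.n_points,
            "genotype": [ann.genotype or ""] * ann.n_points,
            "x": [repr(x) for x, _ in ann.points],
            "y": [repr(y) for _, y in ann.points],
        },
        columns=CSV_COLUMNS,
    )
    frame.to_csv(path, index=False)
    return path


def read_points_csv(
    path: str | Path,
    width: Optional[int] = None,
    height: Optional[int] = None,
) -> PointAnnotation:
    """Read a ``plant_id,genotype,x,y`` CSV back into a :class:`PointAnnotation`.

    Image dimensions are not stored in the CSV; pass them explicitly to
    re-enable bounds checking.  A malformed coordinate raises
    :class:`ValidationError` naming the offending data row (1-based, header
    excluded).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing CSV column(s) {missing}")

    points: list[tuple[float, float]] = []
    for row_no, (xs, ys) in enumerate(zip(frame["x"], frame["y"]), start=1):
        try:
            points.append((float(xs), float(ys)))
        except ValueError as exc:
            raise ValidationError(
                f"{path}: malformed coordinate at data row {row_no}: x={xs!r} y={ys!r}"
            ) from exc

    plant_id = str(frame["plant_id"].iloc[0]) if len(frame) else path.stem
    genotype = (str(frame["genotype"].iloc[0]) or None) if len(frame) else None
    return PointAnnotation(
        plant_id=plant_id, points=points, width=width, height=height, genotype=genotype
    )


def write_metrics_report(
    metrics: Mapping[str, float], path: str | Path, table_path: Optional[str | Path] = None
) -> Path:
    """Serialize a metric mapping as JSON plus a human-readable text table.

    Metric names must come from :data:`KNOWN_METRICS`.  The table is written
    next to the JSON file (``<stem>.txt``) unless ``table_path`` is given.
    """
    if not metrics:
        raise ValidationError("empty metrics mapping")
    unknown = sorted(set(metrics) - KNOWN_METRICS)
    if unknown:
        raise ValidationError(
            f"unknown metric name(s) {unknown}; expected a subset of {sorted(KNOWN_METRICS)}"
        )
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({k: float(v) for k, v in metrics.items()}, fh, indent=1)

    table_path = Path(table_path) if table_path else path.with_suffix(".txt")
    name_w = max(len(k) for k in metrics)
    lines = [f"{k:<{name_w}}  {float(v):.6g}" for k, v in metrics.items()]
    table_path.write_text("\n".join(lines) + "\n")
    return path


def read_metrics_report(path: str | Path) -> dict[str, float]:
    with open(path) as fh:
        return {str(k): float(v) for k, v in json.load(fh).items()}
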