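"""Point-level evaluation: one-to-one matching, localization and counting metrics.

A predicted point counts as a true positive when it is matched one-to-one to
a ground-truth point within a pixel-distance threshold (default 25 px, the
typical spacing of neighboring seeds at the native image scale; it is a
plain config value here and should be rescaled with the imagery).  Matching
is globally greedy: all within-threshold candidate pairs are sorted by
ascending distance (ties by ground-truth index, then prediction index) and
accepted whenever both endpoints are still free.  The result is
deterministic, one-to-one, and maximal — no additional within-threshold
pair of free endpoints remains.

Localization metrics: per-image MED (mean Euclidean distance over matched
pairs), its dataset mean over images with at least one match, and
precision / recall / F1 from TP/FP/FN pooled across images (per-image
values are reported as well, since either aggregation is defensible).
Counting metrics compare per-image counts: MAE, RMSE, and R^2 about the
mean of the ground-truth counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from msanet.errors import ValidationError

DEFAULT_MATCH_THRESHOLD = 25.0

Point = tuple[float, float]


@dataclass
class MatchResult:
    """One-to-one GT-prediction pairs within the threshold, plus residuals."""

    pairs: list[tuple[int, int, float]]  # (gt index, pred index, distance)
    unmatched_gt: list[int]  # false negatives
    unmatched_pred: list[int]  # false positives
    threshold: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)

    @property
    def med(self) -> Optional[float]:
        """Mean Euclidean distance over matched pairs; None when match-free."""
        if not self.pairs:
            return None
        return float(np.mean([d for _, _, d in self.pairs]))


def match_points(
    gt: Sequence[Point], pred: Sequence[Point], threshold: float = DEFAULT_MATCH_THRESHOLD
) -> MatchResult:
    """Greedy distance-ascending one-to-one matching within ``threshold``."""
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    gt_arr = np.asarray(gt, dtype=np.float64).reshape(-1, 2)
    pred_arr = np.asarray(pred, dtype=np.float64).reshape(-1, 2)

    candidates: list[tuple[float, int, int]] = []
    if len(gt_arr) and len(pred_arr):
        dists = cdist(gt_arr, pred_arr)
        gi_idx, pi_idx = np.nonzero(dists <= threshold)
        candidates = sorted(
            (float(dists[gi, pi]), int(gi), int(pi)) for gi, pi in zip(gi_idx, pi_idx)
        )

    gt_free = [True] * len(gt_arr)
    pred_free = [True] * len(pred_arr)
    pairs: list[tuple[int, int, float]] = []
    for d, gi, pi in candidates:
        if gt_free[gi] and pred_free[pi]:
            pairs.append((gi, pi, d))
            gt_free[gi] = False
            pred_free[pi] = False

    return MatchResult(
        pairs=pairs,
        unmatched_gt=[i for i, free in enumerate(gt_free) if free],
        unmatched_pred=[i for i, free in enumerate(pred_free) if free],
        threshold=float(threshold),
    )


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


@dataclass
class MetricsReport:
    """Pooled localization metrics with per-image detail."""

    med: Optional[float]  # mean of per-image MEDs over images with >= 1 pair
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    n_images: int
    n_images_without_matches: int
    per_image_med: list[Optional[float]] = field(default_factory=list)
    per_image_precision: list[float] = field(default_factory=list)
    per_image_recall: list[float] = field(default_factory=list)

    def as_metric_mapping(self) -> dict[str, float]:
        out = {
            "precision": self.precision,
            "recall": self.recall,
            "F1": self.f1,
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
        }
        if self.med is not None:
            out["MED"] = self.med
        return out


def localization_metrics(matches: Sequence[MatchResult]) -> MetricsReport:
    """Aggregate per-image match results into the localization report.

    Images with zero matched pairs are excluded from the dataset MED (the
    per-image mean distance is undefined there) and counted separately.
    """
    if not matches:
        raise ValidationError("localization_metrics requires at least one image")
    per_med = [m.med for m in matches]
    with_pairs = [v for v in per_med if v is not None]
    tp = sum(m.tp for m in matches)
    fp = sum(m.fp for m in matches)
    fn = sum(m.fn for m in matches)
    precision, recall, f1 = precision_recall_f1(tp, fp, fn)
    per_prf = [precision_recall_f1(m.tp, m.fp, m.fn) for m in matches]
    return MetricsReport(
        med=float(np.mean(with_pairs)) if with_pairs else None,
        precision=precision,
        recall=recall,
        f1=f1,
        tp=tp,
        fp=fp,
        fn=fn,
        n_images=len(matches),
        n_images_without_matches=len(matches) - len(with_pairs),
        per_image_med=per_med,
        per_image_precision=[p for p, _, _ in per_prf],
        per_image_recall=[r for _, r, _ in per_prf],
    )


@dataclass
class CountingMetrics:
    mae: float
    rmse: float
    r2: Optional[float]  # None when the ground-truth counts have zero variance

    @property
    def r2_defined(self) -> bool:
        return self.r2 is not None


def counting_metrics(gt_counts: Sequence[float], pred_counts: Sequence[float]) -> CountingMetrics:
    """MAE, RMSE, and R^2 over per-image counts."""
    gt = np.asarray(gt_counts, dtype=np.float64)
    pred = np.asarray(pred_counts, dtype=np.float64)
    if gt.size == 0 or gt.shape != pred.shape:
        raise ValidationError("counting_metrics requires equal-length non-empty count lists")
    err = gt - pred
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    ss_tot = float(((gt - gt.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return CountingMetrics(mae=mae, rmse=rmse, r2=None)
    r2 = 1.0 - float((err**2).sum()) / ss_tot
    return CountingMetrics(mae=mae, rmse=rmse, r2=r2)


def categorize_detections(
    match: MatchResult, gt: Sequence[Point], pred: Sequence[Point]
) -> dict[str, list[str]]:
    """Label every GT point TP/FN and every predicted point TP/FP."""
    gt_labels = ["FN"] * len(gt)
    pred_labels = ["FP"] * len(pred)
    for gi, pi, _ in match.pairs:
        gt_labels[gi] = "TP"
        pred_labels[pi] = "TP"
    if len(match.pairs) + len(match.unmatched_gt) != len(gt):
        raise ValidationError("MatchResult inconsistent with the ground-truth point set")
    if len(match.pairs) + len(match.unmatched_pred) != len(pred):
        raise ValidationError("MatchResult inconsistent with the predicted point set")
    return {"gt": gt_labels, "pred": pred_labels}
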