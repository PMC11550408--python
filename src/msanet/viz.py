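"""Overlay and profile plots: TP/FP/FN renderings and KDE comparison panels."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from msanet.evaluation import MatchResult, categorize_detections
from msanet.traits import KDEProfile

# detection overlay colors: green TP, blue FP, red FN
TP_COLOR = "#2ca02c"
FP_COLOR = "#1f77b4"
FN_COLOR = "#d62728"


def save_detection_overlay(
    image: np.ndarray,
    gt: Sequence[tuple[float, float]],
    pred: Sequence[tuple[float, float]],
    match: MatchResult,
    path: str | Path,
) -> Path:
    """Render predictions over the image: green TPs, blue FPs, red-cross FNs."""
    labels = categorize_detections(match, gt, pred)
    fig, ax = plt.subplots(figsize=(5, 5 * image.shape[0] / image.shape[1]))
    ax.imshow(image)
    tp = [p for p, lab in zip(pred, labels["pred"]) if lab == "TP"]
    fp = [p for p, lab in zip(pred, labels["pred"]) if lab == "FP"]
    fn = [g for g, lab in zip(gt, labels["gt"]) if lab == "FN"]
    for pts, color, marker, name in (
        (tp, TP_COLOR, "o", "TP"),
        (fp, FP_COLOR, "o", "FP"),
        (fn, FN_COLOR, "x", "FN"),
    ):
        if pts:
            arr = np.asarray(pts)
            ax.scatter(arr[:, 0], arr[:, 1], s=18, c=color, marker=marker, label=name)
    ax.legend(loc="upper right", fontsize=7)
    ax.set_axis_off()
    fig.savefig(Path(path), dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def save_profile_comparison(
    gt_profile: KDEProfile,
    pred_profile: Optional[KDEProfile],
    path: str | Path,
    title: str = "",
) -> Path:
    """Side-by-side vertical-distribution curves, height on the vertical axis."""
    fig, ax = plt.subplots(figsize=(3.2, 4.2))
    ax.plot(gt_profile.density, gt_profile.grid, color="green", label="ground truth")
    if pred_profile is not None:
        ax.plot(pred_profile.density, pred_profile.grid, color="red", label="prediction")
    ax.invert_yaxis()  # image y grows downward; show the top of the plant on top
    ax.set_xlabel("KDE density")
    ax.set_ylabel(f"vertical position ({gt_profile.units})")
    if title:
        ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
    return Path(path)
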