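"""Tracking metrics: center error (TE), per-direction RMSE, and mean IoU.

Clinical loops carry sparse labels (one box every ~10 frames), so every
metric is computed only on the frames where a ground-truth box exists.

* ``TE_j = ||p_j - p_hat_j||_2`` — Euclidean distance between predicted
  and true box centers, per labeled frame; reported as the mean.
* ``RMSE_k = sqrt(mean_j (p_hat_{k;j} - p_{k;j})^2)`` per direction
  k in {lateral (x), axial (y)} over the M labeled frames.  The single
  combined "RMSE" column is this package's convention
  ``sqrt(RMSE_x^2 + RMSE_y^2)`` (the per-direction definition does not
  prescribe one).
* ``IoU_j = |G_hat_j intersect G_j| / |G_hat_j union G_j|`` with boxes as
  half-open rectangles in continuous coordinates; reported as the mean.
* FPS is wall-clock throughput, reported but never asserted — it is
  hardware-dependent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import BoundingBox
from .tracker import TrackResult

__all__ = [
    "tracking_error",
    "rmse_direction",
    "iou",
    "EvalReport",
    "evaluate_run",
    "plot_displacement",
]


def tracking_error(p, p_hat) -> float:
    """Euclidean center distance ``||p - p_hat||_2`` in pixels."""
    p = np.asarray(p, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    return float(np.linalg.norm(p - p_hat))


def rmse_direction(preds: np.ndarray, gts: np.ndarray, axis: str | int) -> float:
    """Per-direction RMSE over labeled frames.

    ``preds``/``gts`` are (M, 2) arrays of (x, y) centers aligned on the
    same labeled frames; ``axis`` is 'x'/'lateral' (0) or 'y'/'axial' (1).
    """
    preds = np.atleast_2d(np.asarray(preds, dtype=float))
    gts = np.atleast_2d(np.asarray(gts, dtype=float))
    if preds.shape != gts.shape:
        raise ValueError(f"shape mismatch {preds.shape} vs {gts.shape}")
    if preds.shape[0] < 1:
        raise ValueError("need at least one labeled frame")
    axis_map = {"x": 0, "lateral": 0, 0: 0, "y": 1, "axial": 1, 1: 1}
    k = axis_map[axis]
    return float(np.sqrt(np.mean((preds[:, k] - gts[:, k]) ** 2)))


def iou(box_a: BoundingBox, box_b: BoundingBox) -> float:
    """Intersection-over-union of two boxes (half-open rectangles)."""
    ax0, ay0, aw, ah = box_a.to_corner()
    bx0, by0, bw, bh = box_b.to_corner()
    ix = max(0.0, min(ax0 + aw, bx0 + bw) - max(ax0, bx0))
    iy = max(0.0, min(ay0 + ah, by0 + bh) - max(ay0, by0))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    if union <= 0:
        return 0.0
    return float(min(max(inter / union, 0.0), 1.0))  # guard float round-off


@dataclass
class EvalReport:
    """Metrics over the labeled frames of one run."""

    n_labeled: int
    mean_te: float
    rmse_x: float
    rmse_y: float
    rmse_combined: float
    mean_iou: float
    fps: float = float("nan")
    per_frame: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_labeled": self.n_labeled,
            "mean_te": self.mean_te,
            "rmse_lateral": self.rmse_x,
            "rmse_axial": self.rmse_y,
            "rmse_combined": self.rmse_combined,
            "mean_iou": self.mean_iou,
            "fps": self.fps,
        }

    def to_json(self, path) -> None:
        payload = dict(self.to_dict())
        payload["per_frame"] = self.per_frame
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def evaluate_run(
    pred: TrackResult | Mapping[int, BoundingBox],
    gt: Mapping[int, BoundingBox],
) -> EvalReport:
    """Score predictions against (possibly sparse) ground-truth boxes.

    Only frames present in both inputs contribute; unlabeled predicted
    frames never change the report.
    """
    pred_boxes = pred.boxes_dict() if isinstance(pred, TrackResult) else dict(pred)
    frames = sorted(set(pred_boxes) & set(gt))
    if not frames:
        raise ValueError("no labeled frame is covered by the predictions")

    preds = np.array([[pred_boxes[f].cx, pred_boxes[f].cy] for f in frames])
    gts = np.array([[gt[f].cx, gt[f].cy] for f in frames])
    tes = np.linalg.norm(preds - gts, axis=1)
    ious = np.array([iou(pred_boxes[f], gt[f]) for f in frames])
    rx = rmse_direction(preds, gts, "x")
    ry = rmse_direction(preds, gts, "y")

    per_frame = {
        int(f): {"te": float(t), "iou": float(v)} for f, t, v in zip(frames, tes, ious)
    }
    fps = pred.fps if isinstance(pred, TrackResult) else float("nan")
    return EvalReport(
        n_labeled=len(frames),
        mean_te=float(tes.mean()),
        rmse_x=rx,
        rmse_y=ry,
        rmse_combined=float(np.hypot(rx, ry)),
        mean_iou=float(ious.mean()),
        fps=fps,
        per_frame=per_frame,
    )


def plot_displacement(
    pred: TrackResult | Mapping[int, BoundingBox],
    gt: Mapping[int, BoundingBox] | None = None,
    ax_pair=None,
):
    """Lateral/axial displacement traces of the tracked center (and ground
    truth, if given) against frame index.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pred_boxes = pred.boxes_dict() if isinstance(pred, TrackResult) else dict(pred)
    frames = sorted(pred_boxes)
    centers = np.array([[pred_boxes[f].cx, pred_boxes[f].cy] for f in frames])

    if ax_pair is None:
        fig, (ax_x, ax_y) = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
    else:
        ax_x, ax_y = ax_pair
        fig = ax_x.figure
    for ax, k, label in ((ax_x, 0, "lateral (x)"), (ax_y, 1, "axial (y)")):
        ax.plot(frames, centers[:, k] - centers[0, k], label="tracked")
        if gt:
            gframes = sorted(gt)
            g = np.array([[gt[f].cx, gt[f].cy] for f in gframes])
            ax.plot(gframes, g[:, k] - g[0, k], "o--", ms=3, label="ground truth")
        ax.set_ylabel(f"{label} displacement (px)")
        ax.legend(loc="upper right", fontsize=8)
    ax_y.set_xlabel("frame index")
    fig.tight_layout()
    return fig
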