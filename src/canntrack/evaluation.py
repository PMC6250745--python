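"""Tracking-accuracy metrics and the OPE / TRE / SRE protocols.

Center error is the per-frame Euclidean distance between predicted and
ground-truth box centers (pixels); overlap is the intersection-over-union
of the axis-aligned boxes.  The precision curve is the fraction of frames
whose center error falls within a distance threshold; the success curve is
the fraction whose overlap exceeds an overlap threshold, and the success
score (AUC) — the area under that curve — equals the mean overlap.

Protocols: OPE runs the tracker once from the first-frame ground truth;
TRE restarts it from evenly spaced temporal segments; SRE perturbs the
initial box spatially (8 shifts of 10% of the box size, 4 scalings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "Trajectory",
    "MetricCurves",
    "center_error",
    "overlap_series",
    "precision_curve",
    "success_curve",
    "auc_score",
    "run_ope",
    "run_tre",
    "run_sre",
    "sre_variants",
]

DIST_THRESHOLDS = np.arange(0.0, 51.0, 1.0)
OVERLAP_THRESHOLDS = np.arange(0.0, 1.0001, 0.05)


def box_center(boxes: np.ndarray) -> np.ndarray:
    """(cx, cy) centers of (x, y, w, h) boxes."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    return boxes[:, :2] + boxes[:, 2:] / 2.0


@dataclass
class Trajectory:
    """Paired predicted and ground-truth boxes over one run."""

    pred: np.ndarray  # (T, 4)
    gt: np.ndarray    # (T, 4)

    def __post_init__(self) -> None:
        self.pred = np.atleast_2d(np.asarray(self.pred, dtype=float))
        self.gt = np.atleast_2d(np.asarray(self.gt, dtype=float))
        if self.pred.shape != self.gt.shape:
            raise InputError(
                f"trajectory length mismatch: {self.pred.shape} vs {self.gt.shape}"
            )
        if len(self.pred) == 0:
            raise InputError("empty trajectory")


@dataclass
class MetricCurves:
    """Per-frame error series and the derived threshold curves."""

    center_errors: np.ndarray
    overlaps: np.ndarray
    dist_thresholds: np.ndarray
    precision: np.ndarray
    overlap_thresholds: np.ndarray
    success: np.ndarray
    mean_center_error: float
    auc: float

    def summary(self) -> dict[str, float]:
        return {"auc": self.auc, "mean_center_error": self.mean_center_error}


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def center_error(traj: Trajectory) -> tuple[np.ndarray, float]:
    """Per-frame Euclidean center distances and their mean."""
    d = np.linalg.norm(box_center(traj.pred) - box_center(traj.gt), axis=1)
    return d, float(d.mean())


def overlap_series(traj: Trajectory) -> np.ndarray:
    """Per-frame intersection-over-union of predicted vs ground-truth boxes.

    Continuous rectangle areas (no pixel rasterization); a zero-area box
    yields overlap 0.
    """
    p, g = traj.pred, traj.gt
    x1 = np.maximum(p[:, 0], g[:, 0])
    y1 = np.maximum(p[:, 1], g[:, 1])
    x2 = np.minimum(p[:, 0] + p[:, 2], g[:, 0] + g[:, 2])
    y2 = np.minimum(p[:, 1] + p[:, 3], g[:, 1] + g[:, 3])
    inter = np.maximum(0.0, x2 - x1) * np.maximum(0.0, y2 - y1)
    area_p = p[:, 2] * p[:, 3]
    area_g = g[:, 2] * g[:, 3]
    union = area_p + area_g - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def precision_curve(
    errors: np.ndarray, thresholds: np.ndarray = DIST_THRESHOLDS
) -> np.ndarray:
    """Fraction of frames with center error within each distance threshold."""
    return (errors[None, :] <= thresholds[:, None]).mean(axis=1)


def success_curve(
    overlaps: np.ndarray, thresholds: np.ndarray = OVERLAP_THRESHOLDS
) -> np.ndarray:
    """Fraction of frames with overlap larger than each threshold."""
    return (overlaps[None, :] > thresholds[:, None]).mean(axis=1)


def auc_score(overlaps: np.ndarray) -> float:
    """Success-plot area under curve, computed as the mean overlap.

    The success curve is the survival function of the overlap distribution,
    so its integral over [0, 1] equals the mean overlap exactly.
    """
    return float(np.asarray(overlaps).mean())


def compute_metrics(traj: Trajectory) -> MetricCurves:
    errs, mean_err = center_error(traj)
    ious = overlap_series(traj)
    return MetricCurves(
        center_errors=errs,
        overlaps=ious,
        dist_thresholds=DIST_THRESHOLDS.copy(),
        precision=precision_curve(errs),
        overlap_thresholds=OVERLAP_THRESHOLDS.copy(),
        success=success_curve(ious),
        mean_center_error=mean_err,
        auc=auc_score(ious),
    )


# --------------------------------------------------------------------------
# Protocols
#
# A tracker is a callable ``tracker(frames, init_box) -> (T, 4) boxes`` run
# over grayscale frames with the first-frame box as initialization.
# --------------------------------------------------------------------------

def run_ope(tracker, frames: list[np.ndarray], gt_boxes: np.ndarray) -> MetricCurves:
    """One-pass evaluation: a single run initialized from the first box."""
    pred = tracker(frames, tuple(gt_boxes[0]))
    return compute_metrics(Trajectory(pred=pred, gt=gt_boxes))


def _aggregate(runs: list[MetricCurves]) -> MetricCurves:
    """Average metrics over protocol runs (pointwise over curves)."""
    all_err = np.concatenate([r.center_errors for r in runs])
    all_iou = np.concatenate([r.overlaps for r in runs])
    return MetricCurves(
        center_errors=all_err,
        overlaps=all_iou,
        dist_thresholds=DIST_THRESHOLDS.copy(),
        precision=np.mean([r.precision for r in runs], axis=0),
        overlap_thresholds=OVERLAP_THRESHOLDS.copy(),
        success=np.mean([r.success for r in runs], axis=0),
        mean_center_error=float(np.mean([r.mean_center_error for r in runs])),
        auc=float(np.mean([r.auc for r in runs])),
    )


def tre_segment_starts(n_frames: int, n_segments: int) -> list[int]:
    """Deterministic, evenly spaced segment start frames."""
    starts = np.unique(
        np.floor(np.linspace(0, n_frames - 2, n_segments, endpoint=True)).astype(int)
    )
    return [int(s) for s in starts]


def run_tre(
    tracker, frames: list[np.ndarray], gt_boxes: np.ndarray, n_segments: int = 20
) -> MetricCurves:
    """Temporal-robustness evaluation: suffix runs from each segment start."""
    if n_segments < 1:
        raise InputError("n_segments must be >= 1")
    runs = []
    for s in tre_segment_starts(len(frames), n_segments):
        if s >= len(frames) - 1:
            import logging
            logging.getLogger(__name__).warning("segment start %d skipped", s)
            continue
        pred = tracker(frames[s:], tuple(gt_boxes[s]))
        runs.append(compute_metrics(Trajectory(pred=pred, gt=gt_boxes[s:])))
    return _aggregate(runs)


def sre_variants(box: tuple[float, float, float, float]) -> list[tuple[float, float, float, float]]:
    """The 12 spatial perturbations of an initial box.

    8 center shifts by 10% of the box size in the compass directions and
    4 scalings by {0.8, 0.9, 1.1, 1.2} about the center.
    """
    x, y, w, h = box
    out = []
    for dx, dy in [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]:
        out.append((x + 0.1 * w * dx, y + 0.1 * h * dy, w, h))
    for s in (0.8, 0.9, 1.1, 1.2):
        cx, cy = x + w / 2.0, y + h / 2.0
        out.append((cx - s * w / 2.0, cy - s * h / 2.0, s * w, s * h))
    return out


def run_sre(
    tracker, frames: list[np.ndarray], gt_boxes: np.ndarray,
    variants: list[tuple[float, float, float, float]] | None = None,
) -> MetricCurves:
    """Spatial-robustness evaluation: runs from perturbed initial boxes."""
    if variants is None:
        variants = sre_variants(tuple(gt_boxes[0]))
    runs = []
    for box in variants:
        pred = tracker(frames, box)
        runs.append(compute_metrics(Trajectory(pred=pred, gt=gt_boxes)))
    return _aggregate(runs)


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

def metrics_to_csv(m: MetricCurves, path) -> None:
    """Per-frame series as CSV (frame, center_error, overlap)."""
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame", "center_error", "overlap"])
        for t, (e, o) in enumerate(zip(m.center_errors, m.overlaps)):
            wr.writerow([t, f"{e:.6g}", f"{o:.6g}"])


def plot_curves(m: MetricCurves, path_prefix) -> None:
    """Render OTB-style precision and success plots to PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(m.dist_thresholds, m.precision)
    axes[0].set(xlabel="center-error threshold (px)", ylabel="precision",
                title="Precision plot", ylim=(0, 1.02))
    axes[1].plot(m.overlap_thresholds, m.success)
    axes[1].set(xlabel="overlap threshold", ylabel="success rate",
                title=f"Success plot (AUC = {m.auc:.3f})", ylim=(0, 1.02))
    fig.tight_layout()
    fig.savefig(f"{path_prefix}_curves.png", dpi=120)
    plt.close(fig)
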