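"""Segmentation and localization evaluation.

Segmentation quality is scored from a pixel-level confusion matrix with the
macro-averaged metrics customary in semantic segmentation: mean pixel
accuracy (mPA), mean intersection-over-union (mIoU), macro precision (MP)
and macro recall (MR).  Localization quality is scored in image space by the
combined pixel error e = sqrt(e_x^2 + e_y^2) against a labeled best-picking
region, and in camera space by mean absolute depth/lateral errors after
pinhole back-projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyConfusionError
from .geometry import Point2D


def confusion(pred: np.ndarray, truth: np.ndarray, num_classes: int) -> np.ndarray:
    """Pixel cross-tabulation; entry [i, j] counts true class i predicted j."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, a in (("pred", pred), ("truth", truth)):
        if a.min() < 0 or a.max() >= num_classes:
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    idx = truth.ravel().astype(np.int64) * num_classes + pred.ravel().astype(np.int64)
    return np.bincount(idx, minlength=num_classes**2).reshape(num_classes, num_classes)


def _per_class(cm: np.ndarray):
    cm = np.asarray(cm, dtype=float)
    if cm.sum() == 0:
        raise EmptyConfusionError("confusion matrix has no counts")
    diag = np.diag(cm)
    row = cm.sum(axis=1)  # pixels truly of class i
    col = cm.sum(axis=0)  # pixels predicted as class i
    present = (row + col) > 0  # classes absent from both are excluded
    return diag, row, col, present


def _macro(values: np.ndarray, present: np.ndarray) -> float:
    return float(100.0 * values[present].mean())


def mPA(cm: np.ndarray) -> float:
    """Mean pixel accuracy: average over classes of p_ii / sum_j p_ij (%)."""
    diag, row, _, present = _per_class(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
    return _macro(acc, present)


def mIoU(cm: np.ndarray) -> float:
    """Mean intersection over union: p_ii / (row_i + col_i - p_ii) (%)."""
    diag, row, col, present = _per_class(cm)
    union = row + col - diag
    iou = np.where(union > 0, diag / np.maximum(union, 1), 0.0)
    return _macro(iou, present)


def MP(cm: np.ndarray) -> float:
    """Macro precision: average of p_ii / sum_j p_ji over classes (%)."""
    diag, _, col, present = _per_class(cm)
    prec = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
    return _macro(prec, present)


def MR(cm: np.ndarray) -> float:
    """Macro recall: average of p_ii / sum_j p_ij over classes (%).

    Algebraically identical to :func:`mPA`; exposed separately because both
    names are standard reporting columns.
    """
    return mPA(cm)


def per_class_iou_accuracy(cm: np.ndarray):
    """(iou, accuracy) fractions per present class, for diagnostics."""
    diag, row, col, present = _per_class(cm)
    union = row + col - diag
    iou = np.where(union > 0, diag / np.maximum(union, 1), 0.0)
    acc = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
    return iou[present], acc[present]


@dataclass(frozen=True)
class BestRegion:
    """Rectangular ground-truth best-picking region (inclusive pixel spans).

    The branch center axis around the necking is marked as a small rectangle
    (typically 30 rows x 10 columns); a point ground truth is the degenerate
    1x1 region.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self):
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError("BestRegion spans must be non-decreasing")

    @classmethod
    def from_point(cls, p: Point2D) -> "BestRegion":
        return cls(p.x, p.x, p.y, p.y)

    @classmethod
    def around(cls, p: Point2D, width: float = 10.0, height: float = 30.0) -> "BestRegion":
        return cls(p.x - width / 2, p.x + width / 2, p.y - height / 2, p.y + height / 2)


@dataclass(frozen=True)
class PixelError:
    """Per-axis and combined pixel error, e = sqrt(e_x^2 + e_y^2)."""

    e_x: float
    e_y: float
    e: float
    best: BestRegion
    predicted: Point2D


def _axis_error(lo: float, hi: float, v: float) -> float:
    """min over the span [lo, hi] of |span - v|; zero inside the span."""
    if lo <= v <= hi:
        return 0.0
    return min(abs(lo - v), abs(hi - v))


def pixel_error(best: BestRegion | Point2D, pred: Point2D) -> PixelError:
    """Combined pixel error of a predicted picking point.

    ``e_x`` (resp. ``e_y``) is the minimum horizontal (vertical) distance
    from the prediction to the best region's column (row) span, zero when
    the coordinate falls inside the span.
    """
    if isinstance(best, Point2D):
        best = BestRegion.from_point(best)
    ex = _axis_error(best.x_min, best.x_max, pred.x)
    ey = _axis_error(best.y_min, best.y_max, pred.y)
    return PixelError(e_x=ex, e_y=ey, e=float(np.hypot(ex, ey)), best=best, predicted=pred)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels."""

    f_x: float
    f_y: float
    c_x: float
    c_y: float

    def __post_init__(self):
        if self.f_x <= 0 or self.f_y <= 0:
            raise ValueError("focal lengths must be positive")


def pixel_to_camera(u: float, v: float, depth: float, intr: CameraIntrinsics) -> np.ndarray:
    """Back-project pixel (u, v) at ``depth`` (mm) into the camera frame."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    x = (u - intr.c_x) * depth / intr.f_x
    y = (v - intr.c_y) * depth / intr.f_y
    return np.array([x, y, depth], dtype=float)


def camera_to_pixel(p: np.ndarray, intr: CameraIntrinsics) -> tuple[float, float]:
    """Forward pinhole projection, the inverse of :func:`pixel_to_camera`."""
    x, y, z = np.asarray(p, dtype=float)
    if z <= 0:
        raise ValueError("point must be in front of the camera")
    return (intr.f_x * x / z + intr.c_x, intr.f_y * y / z + intr.c_y)


def camera_to_global(p: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Rigid transform R p + t into the global (calibration-plate) frame."""
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation must be 3x3 orthonormal")
    return R @ np.asarray(p, dtype=float) + np.asarray(translation, dtype=float)


@dataclass(frozen=True)
class DepthEvalRecord:
    """One measurement pairing camera and manual references (all mm).

    ``z_cp``/``x_cp``: picking-point coordinates measured by the depth camera;
    ``z_gt``: manually measured depth; ``x_op``: X of the calibration-plate
    reference point; ``l_m``: manually measured reference-to-target distance.
    """

    z_cp: float
    x_cp: float
    z_gt: float
    x_op: float
    l_m: float


def depth_errors(records: Sequence[DepthEvalRecord]) -> tuple[float, float]:
    """Mean absolute visual-localization errors (E_Z, E_X) in mm.

    E_Z = mean_m |Z(CP)_m - Z(GT)_m|;  E_X = mean_m |X(CP)_m - X(OP)_m - L_m|.
    Absolute deviations are used so opposite-signed errors cannot cancel.
    """
    if not records:
        raise ValueError("depth_errors requires at least one record")
    ez = float(np.mean([abs(r.z_cp - r.z_gt) for r in records]))
    ex = float(np.mean([abs(r.x_cp - r.x_op - r.l_m) for r in records]))
    return ez, ex
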