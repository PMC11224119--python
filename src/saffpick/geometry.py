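"""Barycenter-projection localization of the filament picking point.

The picking point of an opened safflower sits at the *necking*, the junction
between the harvestable filament bundle (class 1) and the fruit ball
(class 2) directly above the supporting branch (class 3).  Given a per-pixel
class map this module recovers that point geometrically:

1. take the largest connected component of the filament and of the fruit
   ball and compute their barycenters ``P1``, ``P2``;
2. open a rectangular region of interest (ROI) below the fruit ball where
   the branch must lie;
3. detect the branch as the probabilistic-Hough line segment whose
   supporting line minimizes the summed point-line distance to the two
   barycenters;
4. orthogonally project both barycenters onto that line and return the
   midpoint of the projections as the picking point ``Pc``.

Coordinate convention throughout the package: ``x`` is the column, ``y`` the
row, origin at the top-left corner, 0-based.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.transform import probabilistic_hough_line

from .errors import (
    ClassMissingError,
    EmptyMaskError,
    NoBranchLineError,
    RoiDegenerateError,
    RoiTooSmallError,
    SaffpickError,
)

# label-map class ids
BACKGROUND, FILAMENT, FRUIT_BALL, BRANCH = 0, 1, 2, 3

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Point2D:
    """A pixel-coordinate point; ``x`` = column, ``y`` = row."""

    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("Point2D coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class LineSegment:
    """Directed segment between two distinct endpoints ``q1``, ``q2``."""

    q1: Point2D
    q2: Point2D

    def __post_init__(self):
        if self.q1.x == self.q2.x and self.q1.y == self.q2.y:
            raise ValueError("LineSegment endpoints must differ")

    @property
    def length(self) -> float:
        return float(np.hypot(self.q2.x - self.q1.x, self.q2.y - self.q1.y))


@dataclass(frozen=True)
class RectROI:
    """Half-open pixel rectangle ``[x_min, x_max) × [y_min, y_max)``."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("RectROI must have positive extent")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y_max - self.y_min, self.x_max - self.x_min)

    def crop(self, array: np.ndarray) -> np.ndarray:
        return array[self.y_min : self.y_max, self.x_min : self.x_max]


@dataclass(frozen=True)
class ComponentMask:
    """A single 8-connected component as a boolean map."""

    mask: np.ndarray

    def __post_init__(self):
        if self.mask.dtype != bool or self.mask.ndim != 2:
            raise ValueError("ComponentMask.mask must be a 2-D boolean array")
        if not self.mask.any():
            raise EmptyMaskError("component mask has no pixels")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class HoughParams:
    """Probabilistic Hough transform tuning.

    ``threshold`` is the accumulator vote threshold, ``min_length`` the
    shortest accepted segment (px), ``max_gap`` the largest bridged gap (px),
    ``theta_step_deg`` the angular resolution.
    """

    threshold: int = 30
    min_length: int = 20
    max_gap: int = 5
    theta_step_deg: float = 1.0
    seed: int = 0

    def thetas(self) -> np.ndarray:
        n = int(round(180.0 / self.theta_step_deg))
        return np.linspace(-np.pi / 2.0, np.pi / 2.0, n, endpoint=False)


@dataclass(frozen=True)
class LocateConfig:
    hough: HoughParams = field(default_factory=HoughParams)
    roi_margin: float = 0.1
    edge_threshold: float | str = "otsu"

    @classmethod
    def from_dict(cls, d: dict) -> "LocateConfig":
        d = dict(d or {})
        hough = HoughParams(**d.pop("hough", {}))
        return cls(hough=hough, **d)


@dataclass(frozen=True)
class PickingResult:
    """Full output of :func:`locate` for one scene."""

    filament_barycenter: Point2D
    ball_barycenter: Point2D
    chosen_line: LineSegment
    proj_filament: Point2D
    proj_ball: Point2D
    picking_point: Point2D
    min_distance: float


@contextmanager
def _stage(name: str):
    """Re-raise package errors with the pipeline stage name prepended."""
    try:
        yield
    except SaffpickError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc


def largest_component(label_map: np.ndarray, class_id: int) -> ComponentMask:
    """Largest 8-connected component of ``class_id`` in ``label_map``.

    Ties on pixel count are broken by the smallest component label, which is
    deterministic for a given input.
    """
    if class_id not in (FILAMENT, FRUIT_BALL, BRANCH):
        raise ValueError(f"class_id must be 1, 2 or 3, got {class_id}")
    binary = np.asarray(label_map) == class_id
    if not binary.any():
        raise ClassMissingError(f"class {class_id} absent from label map")
    labeled, n = ndimage.label(binary, structure=_EIGHT_CONNECTED)
    counts = np.bincount(labeled.ravel())[1 : n + 1]
    best = int(np.argmax(counts)) + 1  # argmax returns first max -> lowest label
    return ComponentMask(mask=labeled == best)


def barycenter(mask: ComponentMask | np.ndarray) -> Point2D:
    """Arithmetic mean of the member pixel coordinates (center of mass)."""
    m = mask.mask if isinstance(mask, ComponentMask) else np.asarray(mask, bool)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise EmptyMaskError("cannot take barycenter of an empty mask")
    return Point2D(x=float(cols.mean()), y=float(rows.mean()))


def branch_roi(
    filament_bc: Point2D,
    ball_bc: Point2D,
    ball_mask: ComponentMask,
    image_shape: tuple[int, int],
    margin: float = 0.1,
) -> RectROI:
    """Rectangle below the fruit ball in which the branch is searched.

    Columns span the ball's horizontal extent widened by ``margin`` times the
    left-right pole distance on each side; rows run from the lowest contour
    pixel of the ball to the image bottom.  The strip must be at least two
    rows tall to be searchable, otherwise the ROI is degenerate.
    """
    h, w = image_shape[:2]
    rows, cols = np.nonzero(ball_mask.mask)
    left, right = int(cols.min()), int(cols.max())
    lowest = int(rows.max())
    margin_px = int(round(margin * (right - left)))
    x_min = max(0, left - margin_px)
    x_max = min(w, right + 1 + margin_px)
    y_min, y_max = lowest, h
    if y_max - y_min < 2 or x_max - x_min < 1:
        raise RoiDegenerateError(
            f"no searchable strip below the fruit ball (rows [{y_min},{y_max}))"
        )
    return RectROI(x_min=x_min, y_min=y_min, x_max=x_max, y_max=y_max)


def gradient_magnitude(gray_roi: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude sqrt(f_w^2 + f_h^2).

    f_w(x,y) = [f(x+1,y) - f(x-1,y)]/2 and f_h analogously; borders use
    replicated-edge padding so the difference is well defined everywhere.
    """
    g = np.asarray(gray_roi, dtype=float)
    if g.ndim != 2 or g.shape[0] < 3 or g.shape[1] < 3:
        raise RoiTooSmallError(f"ROI must be at least 3x3, got {g.shape}")
    p = np.pad(g, 1, mode="edge")
    fw = 0.5 * (p[1:-1, 2:] - p[1:-1, :-2])
    fh = 0.5 * (p[2:, 1:-1] - p[:-2, 1:-1])
    return np.sqrt(fw * fw + fh * fh)


def binarize_edges(grad: np.ndarray, threshold: float | str = "otsu") -> np.ndarray:
    """Threshold a gradient map into a binary edge map.

    ``threshold`` may be a number (pixel true iff grad >= threshold) or
    ``"otsu"`` to maximize between-class variance over a 256-bin histogram.
    A flat gradient map has no edges and yields an all-false map.
    """
    g = np.asarray(grad, dtype=float)
    if threshold == "otsu":
        if np.ptp(g) == 0.0:
            return np.zeros_like(g, dtype=bool)
        threshold = threshold_otsu(g, nbins=256)
        return g > threshold
    return g >= float(threshold)


def _segment_support(edge_map: np.ndarray, seg: LineSegment, tol: float = 1.0) -> int:
    """Count edge pixels within ``tol`` px of the segment (its vote score)."""
    rows, cols = np.nonzero(edge_map)
    if rows.size == 0:
        return 0
    p = np.stack([cols, rows], axis=1).astype(float)
    a = seg.q1.as_array()
    d = seg.q2.as_array() - a
    L2 = float(d @ d)
    t = np.clip((p - a) @ d / L2, 0.0, 1.0)
    closest = a + t[:, None] * d
    dist = np.hypot(*(p - closest).T)
    return int((dist <= tol).sum())


def hough_line_segments(
    edge_map: np.ndarray, params: HoughParams | None = None
) -> list[LineSegment]:
    """Probabilistic Hough line segments, strongest support first.

    Segments are scored by the number of edge pixels within 1 px of the
    segment and returned in decreasing score order (ties: longer first).
    An empty result is not an error; the caller decides.
    """
    params = params or HoughParams()
    edge = np.asarray(edge_map, bool)
    raw = probabilistic_hough_line(
        edge,
        threshold=params.threshold,
        line_length=params.min_length,
        line_gap=params.max_gap,
        theta=params.thetas(),
        rng=params.seed,
    )
    segments = []
    for (x0, y0), (x1, y1) in raw:
        if (x0, y0) == (x1, y1):
            continue
        seg = LineSegment(Point2D(float(x0), float(y0)), Point2D(float(x1), float(y1)))
        segments.append(seg)
    scored = [(_segment_support(edge, s), s.length, -i, s) for i, s in enumerate(segments)]
    scored.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
    return [s for *_, s in scored]


def point_to_line_distance(p: Point2D, seg: LineSegment) -> float:
    """Perpendicular distance from ``p`` to the infinite supporting line.

    Computed as |(q2-q1) x (p-q1)| / |q2-q1|, which agrees with the slope
    form L_b = |m·x + c − y| / sqrt(1+m²) whenever the line is not vertical
    and stays well defined when it is.
    """
    a, b = seg.q1.as_array(), seg.q2.as_array()
    d = b - a
    cross = d[0] * (p.y - a[1]) - d[1] * (p.x - a[0])
    return float(abs(cross) / np.hypot(*d))


def select_picking_line(
    filament_bc: Point2D, ball_bc: Point2D, lines: Sequence[LineSegment]
) -> LineSegment:
    """Segment minimizing the summed barycenter-to-line distance min(L_b).

    Ties (within 1e-9 px) go to the longer segment, then to input order.
    """
    if not lines:
        raise NoBranchLineError("no candidate branch line segments")
    sums = [
        point_to_line_distance(filament_bc, s) + point_to_line_distance(ball_bc, s)
        for s in lines
    ]
    best = min(sums)
    tied = [i for i, v in enumerate(sums) if v <= best + 1e-9]
    tied.sort(key=lambda i: (-lines[i].length, i))
    return lines[tied[0]]


def project_point(p: Point2D, seg: LineSegment) -> Point2D:
    """Orthogonal projection of ``p`` onto the supporting line (not clamped)."""
    a, b = seg.q1.as_array(), seg.q2.as_array()
    d = b - a
    t = float((p.as_array() - a) @ d / (d @ d))
    q = a + t * d
    return Point2D(x=float(q[0]), y=float(q[1]))


def picking_point(proj1: Point2D, proj2: Point2D) -> Point2D:
    """Coordinate-wise midpoint of the two barycenter projections."""
    return Point2D(x=0.5 * (proj1.x + proj2.x), y=0.5 * (proj1.y + proj2.y))


def locate(
    label_map: np.ndarray,
    image: np.ndarray,
    config: LocateConfig | None = None,
) -> PickingResult:
    """Run the full localization chain on one scene.

    Stages: largest components and barycenters of filament and fruit ball,
    branch ROI, grayscale gradient, edge binarization, Hough segments,
    line selection, projections, midpoint.  Errors raised inside a stage are
    re-raised with the stage name prefixed.
    """
    config = config or LocateConfig()
    label_map = np.asarray(label_map)
    with _stage("components"):
        # branch pixels must exist even though the line itself comes from edges
        if not (label_map == BRANCH).any():
            raise ClassMissingError(f"class {BRANCH} absent from label map")
        filament = largest_component(label_map, FILAMENT)
        ball = largest_component(label_map, FRUIT_BALL)
    with _stage("barycenters"):
        p1 = barycenter(filament)
        p2 = barycenter(ball)
    with _stage("roi"):
        roi = branch_roi(p1, p2, ball, label_map.shape, margin=config.roi_margin)
    with _stage("edges"):
        img = np.asarray(image, dtype=float)
        gray = rgb2gray(img / 255.0 if img.max() > 1.5 else img) if img.ndim == 3 else img
        grad = gradient_magnitude(roi.crop(gray))
        edges = binarize_edges(grad, config.edge_threshold)
    with _stage("hough"):
        local = hough_line_segments(edges, config.hough)
        offset = np.array([roi.x_min, roi.y_min], dtype=float)
        lines = [
            LineSegment(
                Point2D(*(s.q1.as_array() + offset)),
                Point2D(*(s.q2.as_array() + offset)),
            )
            for s in local
        ]
        if not lines:
            raise NoBranchLineError("Hough transform found no branch line in ROI")
    with _stage("selection"):
        chosen = select_picking_line(p1, p2, lines)
        min_dist = point_to_line_distance(p1, chosen) + point_to_line_distance(p2, chosen)
    proj1 = project_point(p1, chosen)
    proj2 = project_point(p2, chosen)
    pc = picking_point(proj1, proj2)
    return PickingResult(
        filament_barycenter=p1,
        ball_barycenter=p2,
        chosen_line=chosen,
        proj_filament=proj1,
        proj_ball=proj2,
        picking_point=pc,
        min_distance=float(min_dist),
    )
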