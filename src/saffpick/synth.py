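"""Seeded generator of safflower-like scenes for desk-scale testing.

A scene emulates the canonical geometry of an opened safflower viewed from a
harvesting robot: a near-vertical branch, an elliptical fruit ball sitting
on top of it, and a textured filament tuft opening on the ball, all against
a near-color vegetation background.  Each sample carries analytic ground
truth — the organ barycenters and the necking point (intersection of the
branch axis with the filament/fruit-ball boundary) — so segmentation and
localization can be verified end to end without field data.

The generator is a pure function of its spec (including the seed): the same
spec yields bit-identical images and label maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

from .errors import SpecOutOfBoundsError
from .geometry import BACKGROUND, BRANCH, FILAMENT, FRUIT_BALL, Point2D

WEATHER_REGIMES = ("sunny-light", "sunny-backlight", "overcast", "cloudy")

# organ base colors (RGB); greens are deliberately close to the background
# so the scenes exercise near-color discrimination
_BG_COLOR = np.array([95.0, 135.0, 75.0])
_BRANCH_COLOR = np.array([70.0, 90.0, 40.0])
_BALL_COLOR = np.array([110.0, 150.0, 70.0])
_FILAMENT_COLOR = np.array([235.0, 150.0, 40.0])
_FILAMENT_DEEP = np.array([200.0, 80.0, 25.0])
_LEAF_COLOR = np.array([85.0, 120.0, 60.0])


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene (pixels unless noted).

    ``None`` geometric fields are drawn from their default ranges using the
    spec's seed: branch angle from U[-10, 10] degrees off vertical, ball
    center uniformly from the central image region.
    """

    height: int = 480
    width: int = 640
    branch_angle_deg: float | None = None
    branch_width: float = 6.0
    branch_length: float = 180.0
    ball_semi_axes: tuple[float, float] = (28.0, 26.0)  # (horizontal, vertical)
    filament_radius: float = 26.0
    petal_count: int = 12
    ball_center: tuple[float, float] | None = None  # (x, y)
    noise_sigma: float = 3.0
    weather: str = "sunny-light"
    occlusion: float = 0.0
    depth_mm: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.weather not in WEATHER_REGIMES:
            raise ValueError(f"unknown weather {self.weather!r}")
        if not (0.0 <= self.occlusion <= 0.3):
            raise ValueError("occlusion must be in [0, 0.3]")
        for v in (self.branch_width, self.branch_length, self.filament_radius,
                  *self.ball_semi_axes):
            if v <= 0:
                raise ValueError("geometric sizes must be positive")

    def scaled(self, factor: float) -> "SceneSpec":
        """Scale image size and all geometry by ``factor`` (keeps seed)."""
        return replace(
            self,
            height=max(16, int(round(self.height * factor))),
            width=max(16, int(round(self.width * factor))),
            branch_width=max(2.0, self.branch_width * factor),
            branch_length=self.branch_length * factor,
            ball_semi_axes=(self.ball_semi_axes[0] * factor, self.ball_semi_axes[1] * factor),
            filament_radius=self.filament_radius * factor,
            ball_center=None if self.ball_center is None
            else (self.ball_center[0] * factor, self.ball_center[1] * factor),
        )


@dataclass(frozen=True)
class SceneSample:
    """Rendered scene with analytic ground truth."""

    image: np.ndarray  # uint8 (H, W, 3)
    label_map: np.ndarray  # uint8 (H, W), values 0..3
    gt_necking: Point2D
    gt_filament_bc: Point2D
    gt_ball_bc: Point2D
    spec: SceneSpec
    depth: np.ndarray | None = None  # mm, optional planar depth


def _smooth_noise(rng, h: int, w: int, amplitude: float, cell: int = 16) -> np.ndarray:
    """Low-frequency texture: coarse noise upsampled to full resolution."""
    coarse = rng.normal(0.0, 1.0, (max(2, h // cell + 2), max(2, w // cell + 2)))
    zoomed = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    return amplitude * zoomed[:h, :w]


def _apply_weather(img: np.ndarray, weather: str, h: int, w: int) -> np.ndarray:
    if weather == "sunny-light":
        return (img - 128.0) * 1.05 + 128.0 + 12.0
    if weather == "sunny-backlight":
        yy = np.arange(h, dtype=float)[:, None]
        xx = np.arange(w, dtype=float)[None, :]
        halo = 45.0 * np.exp(-(((yy - 0) / (0.7 * h)) ** 2 + ((xx - w / 2) / (0.8 * w)) ** 2))
        return img * 1.05 + halo[..., None]
    if weather == "overcast":
        return (img - 128.0) * 0.9 + 128.0 - 15.0
    # cloudy
    return (img - 128.0) * 0.95 + 128.0 - 30.0


def generate_scene(spec: SceneSpec) -> SceneSample:
    """Render one scene; deterministic in ``spec`` (seed included)."""
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    angle = spec.branch_angle_deg
    if angle is None:
        angle = float(rng.uniform(-10.0, 10.0))
    theta = np.deg2rad(angle)
    dx, dy = np.sin(theta), np.cos(theta)  # branch axis direction, downward

    a, b = spec.ball_semi_axes
    if spec.ball_center is None:
        cx = float(rng.uniform(0.3 * w, 0.7 * w))
        cy = float(rng.uniform(0.35 * h, 0.55 * h))
    else:
        cx, cy = spec.ball_center

    # analytic anchors along the branch axis
    necking = Point2D(cx - b * dx, cy - b * dy)
    fil_c = Point2D(necking.x - spec.filament_radius * dx,
                    necking.y - spec.filament_radius * dy)
    branch_end = Point2D(cx + spec.branch_length * dx, cy + spec.branch_length * dy)

    r_f = spec.filament_radius
    top_y = fil_c.y - r_f
    extremes = [
        (fil_c.x - r_f, top_y), (fil_c.x + r_f, top_y),
        (cx - a, cy), (cx + a, cy),
        (branch_end.x, branch_end.y),
    ]
    for ex, ey in extremes:
        if not (0 <= ex < w and 0 <= ey < h):
            raise SpecOutOfBoundsError(
                f"scene structure extends outside the {h}x{w} image at ({ex:.1f},{ey:.1f})"
            )

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    label = np.zeros((h, w), dtype=np.uint8)

    # branch: thick segment from ball center downward
    px, py = xx - cx, yy - cy
    t = np.clip(px * dx + py * dy, 0.0, spec.branch_length)
    dist_branch = np.hypot(px - t * dx, py - t * dy)
    label[dist_branch <= spec.branch_width / 2.0] = BRANCH

    # fruit ball: axis-aligned ellipse, overwrites the branch top
    in_ball = (px / a) ** 2 + (py / b) ** 2 <= 1.0
    label[in_ball] = FRUIT_BALL

    # filament tuft: disk tangent to the ball top along the axis
    fil_d2 = (xx - fil_c.x) ** 2 + (yy - fil_c.y) ** 2
    in_fil = fil_d2 <= r_f**2
    label[in_fil] = FILAMENT

    # image: near-color background with low-frequency texture
    img = np.empty((h, w, 3), dtype=float)
    img[:] = _BG_COLOR
    img += _smooth_noise(rng, h, w, amplitude=10.0)[..., None]
    img[label == BRANCH] = _BRANCH_COLOR
    img[label == FRUIT_BALL] = _BALL_COLOR
    # radial petal strokes give the filament a texture distinct from the ball
    phi = np.arctan2(yy - fil_c.y, xx - fil_c.x)
    petal = 0.5 + 0.5 * np.cos(spec.petal_count * phi)
    fil_color = (_FILAMENT_COLOR[None, :] * petal[in_fil, None]
                 + _FILAMENT_DEEP[None, :] * (1.0 - petal[in_fil, None]))
    img[in_fil] = fil_color

    if spec.occlusion > 0.0:
        # a leaf-like ellipse covering ~occlusion of the structure area
        struct = label != BACKGROUND
        area = float(struct.sum()) * spec.occlusion
        rr = float(np.sqrt(area / np.pi))
        srows, scols = np.nonzero(struct)
        k = int(rng.integers(srows.size))
        ox, oy = float(scols[k]), float(srows[k])
        occ = (xx - ox) ** 2 / (1.6 * rr) ** 2 + (yy - oy) ** 2 / (0.7 * rr) ** 2 <= 1.0
        img[occ] = _LEAF_COLOR
        label[occ] = BACKGROUND

    img = _apply_weather(img, spec.weather, h, w)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    depth = None
    if spec.depth_mm is not None:
        depth = np.full((h, w), float(spec.depth_mm))

    return SceneSample(
        image=img,
        label_map=label,
        gt_necking=necking,
        gt_filament_bc=fil_c,
        gt_ball_bc=Point2D(cx, cy),
        spec=spec,
        depth=depth,
    )


def analytic_areas(spec: SceneSpec, angle_deg: float) -> dict[str, float]:
    """Expected pixel areas of the rendered organs for a concrete angle."""
    a, b = spec.ball_semi_axes
    theta = np.deg2rad(angle_deg)
    d = np.array([np.sin(theta), np.cos(theta)])
    # ellipse radius along the branch axis direction
    r_axis = 1.0 / np.sqrt((d[0] / a) ** 2 + (d[1] / b) ** 2)
    return {
        "filament": np.pi * spec.filament_radius**2,
        "fruit_ball": np.pi * a * b,
        "branch": spec.branch_width * (spec.branch_length - r_axis)
        + np.pi * (spec.branch_width / 2.0) ** 2 / 2.0,  # rounded bottom cap
    }


def generate_dataset(
    n: int,
    spec_ranges: dict | None = None,
    seed: int = 0,
    base_spec: SceneSpec | None = None,
) -> tuple[list[SceneSample], dict[str, list[int]]]:
    """Generate ``n`` scenes and a deterministic 8:2 train/validation split.

    ``spec_ranges`` maps SceneSpec field names to either a (lo, hi) range or
    a sequence of choices, sampled per scene.  The split shuffles indices
    with the dataset seed and assigns the first floor(0.8 n) to training.
    """
    if n < 5:
        raise ValueError("generate_dataset requires n >= 5")
    base = base_spec or SceneSpec()
    spec_ranges = spec_ranges or {"weather": list(WEATHER_REGIMES)}
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        overrides = {"seed": int(rng.integers(2**31))}
        for key, rng_spec in spec_ranges.items():
            if isinstance(rng_spec, (list, tuple)) and len(rng_spec) == 2 and all(
                isinstance(v, (int, float)) and not isinstance(v, bool) for v in rng_spec
            ):
                overrides[key] = float(rng.uniform(*rng_spec))
            else:
                overrides[key] = rng_spec[int(rng.integers(len(rng_spec)))]
        samples.append(generate_scene(replace(base, **overrides)))
    order = rng.permutation(n).tolist()
    n_train = int(np.floor(0.8 * n))
    split = {"train": sorted(order[:n_train]), "val": sorted(order[n_train:])}
    return samples, split


AUGMENT_OPS = ("translate", "rotate", "contrast", "brightness")


def _border_color(image: np.ndarray) -> np.ndarray:
    ring = np.concatenate([image[0], image[-1], image[:, 0], image[:, -1]])
    return np.median(ring, axis=0)


def _rotate_point(p: Point2D, angle_deg: float, h: int, w: int) -> Point2D:
    """Forward map of a point under skimage counter-clockwise rotation."""
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = np.deg2rad(angle_deg)
    x, y = p.x - cx, p.y - cy
    return Point2D(cx + x * np.cos(th) + y * np.sin(th),
                   cy - x * np.sin(th) + y * np.cos(th))


def augment(
    image: np.ndarray,
    label_map: np.ndarray,
    op: str,
    params: dict | None = None,
    seed: int = 0,
):
    """Apply one augmentation; geometric ops move image and labels together.

    Returns ``(image, label_map, transform)`` where ``transform`` maps a
    ground-truth Point2D through the same geometric change (identity for the
    color ops).  Out-of-frame regions become background.
    """
    if op not in AUGMENT_OPS:
        raise ValueError(f"unknown augmentation op {op!r}")
    rng = np.random.default_rng(seed)
    params = dict(params or {})
    img = np.asarray(image)
    lab = np.asarray(label_map)
    h, w = lab.shape

    if op == "translate":
        dx = int(params.get("dx", rng.integers(-w // 8, w // 8 + 1)))
        dy = int(params.get("dy", rng.integers(-h // 8, h // 8 + 1)))
        out_img = np.empty_like(img)
        out_img[:] = _border_color(img).astype(img.dtype)
        out_lab = np.zeros_like(lab)
        src = (slice(max(0, -dy), min(h, h - dy)), slice(max(0, -dx), min(w, w - dx)))
        dst = (slice(max(0, dy), min(h, h + dy)), slice(max(0, dx), min(w, w + dx)))
        out_img[dst] = img[src]
        out_lab[dst] = lab[src]
        return out_img, out_lab, lambda p: Point2D(p.x + dx, p.y + dy)

    if op == "rotate":
        angle = float(params.get("angle", rng.uniform(-15.0, 15.0)))
        cval = _border_color(img)
        chans = [
            _sk_rotate(img[..., c].astype(float), angle, order=1,
                       mode="constant", cval=float(cval[c]), preserve_range=True)
            for c in range(img.shape[2])
        ]
        out_img = np.clip(np.stack(chans, axis=-1), 0, 255).astype(img.dtype)
        out_lab = _sk_rotate(lab.astype(float), angle, order=0, mode="constant",
                             cval=0.0, preserve_range=True).astype(lab.dtype)
        return out_img, out_lab, lambda p: _rotate_point(p, angle, h, w)

    if op == "contrast":
        factor = float(params.get("factor", rng.uniform(0.7, 1.3)))
        mean = img.astype(float).mean()
        out_img = np.clip((img.astype(float) - mean) * factor + mean, 0, 255)
        return out_img.astype(img.dtype), lab.copy(), lambda p: p

    # brightness
    delta = float(params.get("delta", rng.uniform(-35.0, 35.0)))
    out_img = np.clip(img.astype(float) + delta, 0, 255)
    return out_img.astype(img.dtype), lab.copy(), lambda p: p


def expand_dataset(samples: Sequence[SceneSample], seed: int = 0) -> list[SceneSample]:
    """Double a dataset: each scene contributes one augmented variant.

    The augmentation op is drawn per scene; ground-truth points are mapped
    through the same geometric transform.
    """
    if not samples:
        raise ValueError("expand_dataset requires a nonempty input")
    rng = np.random.default_rng(seed)
    out = list(samples)
    for s in samples:
        op = AUGMENT_OPS[int(rng.integers(len(AUGMENT_OPS)))]
        sub = int(rng.integers(2**31))
        img, lab, tf = augment(s.image, s.label_map, op, seed=sub)
        out.append(
            SceneSample(
                image=img,
                label_map=lab,
                gt_necking=tf(s.gt_necking),
                gt_filament_bc=tf(s.gt_filament_bc),
                gt_ball_bc=tf(s.gt_ball_bc),
                spec=s.spec,
                depth=s.depth,
            )
        )
    return out
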