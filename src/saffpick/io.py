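"""Readers, writers and configuration.

Label maps travel as indexed (palette) PNG with the fixed class palette
{0: background, 1: filament, 2: fruit ball, 3: branch}; polygon annotations
in LabelMe-style JSON are rasterized with a pixel-center even-odd rule;
picking points and metrics are exchanged as UTF-8 CSV with '.' decimals.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from matplotlib.path import Path as MplPath
from PIL import Image

from .errors import BadPaletteError
from .geometry import HoughParams, LocateConfig, PickingResult
from .nn.model import ModelConfig
from .nn.train import TrainConfig
from .synth import SceneSpec

NUM_CLASSES = 4
# display palette for indexed label PNGs (class -> RGB)
LABEL_PALETTE = [
    (0, 0, 0),        # background
    (230, 90, 40),    # filament
    (240, 200, 60),   # fruit ball
    (60, 140, 50),    # branch
]

LABELME_CLASSES = {"filament": 1, "fruit ball": 2, "branch": 3}


def write_label_png(label_map: np.ndarray, path: str | Path) -> None:
    """Write a class map as an indexed PNG with the package palette."""
    arr = np.asarray(label_map)
    if arr.min() < 0 or arr.max() >= NUM_CLASSES:
        raise BadPaletteError(f"label values outside 0..{NUM_CLASSES - 1}")
    img = Image.fromarray(arr.astype(np.uint8), mode="P")
    flat = [c for rgb in LABEL_PALETTE for c in rgb]
    img.putpalette(flat + [0] * (768 - len(flat)))
    img.save(path)


def read_label_png(path: str | Path) -> np.ndarray:
    """Read an indexed label PNG; values above class 3 are rejected."""
    img = Image.open(path)
    if img.mode not in ("P", "L"):
        raise BadPaletteError(f"{path}: expected an indexed PNG, got mode {img.mode}")
    arr = np.asarray(img, dtype=np.uint8)
    if arr.max() >= NUM_CLASSES:
        raise BadPaletteError(
            f"{path}: palette index {int(arr.max())} outside classes 0..{NUM_CLASSES - 1}"
        )
    return arr


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def labelme_to_labelmap(json_path: str | Path, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize LabelMe-style polygon annotations into a class map.

    Polygons are filled in file order (later shapes overwrite earlier); a
    pixel belongs to a polygon when its center is inside under the even-odd
    rule.  Unlabeled pixels stay background (0).
    """
    data = json.loads(Path(json_path).read_text())
    h, w = image_shape[:2]
    label = np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    for shape in data.get("shapes", []):
        name = shape.get("label", "")
        if name not in LABELME_CLASSES:
            raise ValueError(f"unknown annotation label {name!r}")
        pts = np.asarray(shape.get("points", []), dtype=float)
        if pts.ndim != 2 or len(pts) < 3:
            raise ValueError(f"polygon for {name!r} needs at least 3 points")
        inside = MplPath(pts).contains_points(centers)
        label.ravel()[inside] = LABELME_CLASSES[name]
    return label.copy()


def write_points_csv(results: dict[str, PickingResult], path: str | Path) -> None:
    """One row per image: barycenters, picking point, summed line distance."""
    rows = []
    for image_id, r in results.items():
        rows.append({
            "image_id": image_id,
            "x1": r.filament_barycenter.x, "y1": r.filament_barycenter.y,
            "x2": r.ball_barycenter.x, "y2": r.ball_barycenter.y,
            "xc": r.picking_point.x, "yc": r.picking_point.y,
            "min_distance": r.min_distance,
        })
    pd.DataFrame(rows, columns=["image_id", "x1", "y1", "x2", "y2", "xc", "yc",
                                "min_distance"]).to_csv(path, index=False)


def read_points_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- configuration --------------------------------------------------------

_SECTION_FIELDS = {
    "model": {f.name for f in dataclasses.fields(ModelConfig)},
    "train": {f.name for f in dataclasses.fields(TrainConfig)},
    "locate": {f.name for f in dataclasses.fields(LocateConfig)},
    "synth": {f.name for f in dataclasses.fields(SceneSpec)} | {"n"},
    "evaluate": {"best_region_width", "best_region_height"},
}
_TOP_KEYS = set(_SECTION_FIELDS) | {"seed", "verbosity"}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated nested run configuration; unknown keys are rejected."""

    model: dict = dataclasses.field(default_factory=dict)
    train: dict = dataclasses.field(default_factory=dict)
    locate: dict = dataclasses.field(default_factory=dict)
    synth: dict = dataclasses.field(default_factory=dict)
    evaluate: dict = dataclasses.field(default_factory=dict)
    seed: int = 42
    verbosity: int = 1

    def model_config(self) -> ModelConfig:
        return ModelConfig.from_dict(self.model) if self.model else ModelConfig()

    def train_config(self, **overrides) -> TrainConfig:
        return TrainConfig(**{**self.train, **overrides})

    def locate_config(self) -> LocateConfig:
        return LocateConfig.from_dict(self.locate)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _SECTION_FIELDS.items():
        keys = set(raw.get(section, {}) or {})
        extra = keys - allowed - ({"hough"} if section == "locate" else set())
        if extra:
            raise ValueError(f"unknown keys in '{section}': {sorted(extra)}")
    if "locate" in raw and "hough" in (raw["locate"] or {}):
        hough_allowed = {f.name for f in dataclasses.fields(HoughParams)}
        extra = set(raw["locate"]["hough"]) - hough_allowed
        if extra:
            raise ValueError(f"unknown keys in 'locate.hough': {sorted(extra)}")
    return RunConfig(**raw)
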