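"""Radiometric image containers and file input/output.

Thermal matrices are accepted either as plain numeric CSV (one value per
cell, degrees Celsius) or as single-channel 16-bit TIFF whose integer
counts map to Celsius through ``celsius = value * scale + offset``
(defaults: scale 0.01, offset 0 — i.e. centi-kelvin-style counts).

ROI sets are written as a JSON document of parametric shapes plus a
companion 16-bit label-mask TIFF (pixel value = ROI label, 0 = none); the
TIFF is the authoritative rasterisation, the JSON the authoritative
geometry, so a write/read round trip reproduces both exactly.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from . import shapes as shp
from .labels import LABEL_NAMES, MAX_ROIS

__all__ = [
    "ThermalImage", "VisualImage", "BinaryMask", "ROI", "ROISet",
    "read_thermal", "read_visual", "write_roi_set", "read_roi_set",
    "extract_temperatures", "write_mask_png", "read_mask_png",
]

REGIONS = ("hand", "shin", "foot")
SIDES = ("left", "right", "both")

DEFAULT_TIFF_SCALE = 0.01
DEFAULT_TIFF_OFFSET = 0.0


@dataclass
class ThermalImage:
    """A temperature matrix in degrees Celsius plus acquisition metadata."""

    pixels: np.ndarray
    region: str
    side: str
    source_path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("thermal image must be a non-empty 2-D matrix")
        bad = np.argwhere(~np.isfinite(self.pixels))
        if bad.size:
            r, c = bad[0]
            raise ValueError(f"non-finite temperature at (row={r}, col={c})")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class VisualImage:
    """An 8-bit RGB photograph co-acquired with a thermal image."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("visual image must be HxWx3, 8-bit")
        if min(self.pixels.shape[:2]) < 1:
            raise ValueError("visual image must be non-empty")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def luminance(self) -> np.ndarray:
        """Rec.601 luma, float in [0, 255]."""
        p = self.pixels.astype(float)
        return 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]


@dataclass
class BinaryMask:
    """Boolean foreground matrix aligned with the image it derives from."""

    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def height(self) -> int:
        return self.bits.shape[0]

    @property
    def width(self) -> int:
        return self.bits.shape[1]

    def area(self) -> int:
        return int(self.bits.sum())


@dataclass
class ROI:
    """One labelled anatomical region: parametric shape + raster mask.

    The mask is the shape's rasterisation intersected with the body-region
    foreground and with the complement of earlier-labelled ROIs of the
    same set (the set-level disjointness rule), so it may be a strict
    subset of ``rasterise(shape)``.
    """

    label: int
    shape: shp.Shape
    mask: BinaryMask
    name: str = ""

    def __post_init__(self):
        if self.label not in LABEL_NAMES:
            raise ValueError(f"unknown ROI label {self.label}")
        if not self.name:
            self.name = LABEL_NAMES[self.label]
        if self.mask.area() == 0:
            raise ValueError(f"ROI {self.name} has an empty mask")


@dataclass
class ROISet:
    """All ROIs extracted from one image; pairwise disjoint, unique labels."""

    rois: list[ROI]
    image_ref: str = ""
    region: str = "hand"

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"bad region {self.region!r}")
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate ROI labels in set")
        if len(self.rois) > MAX_ROIS[self.region]:
            raise ValueError(
                f"{self.region} sets carry at most {MAX_ROIS[self.region]} ROIs")
        overlaps = self.overlapping_pairs()
        if overlaps:
            raise ValueError(f"overlapping ROIs: {overlaps}")

    def overlapping_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(self.rois):
            for b in self.rois[i + 1:]:
                if (a.mask.bits & b.mask.bits).any():
                    out.append((a.name, b.name))
        return out

    def label_mask(self, shape_hw: tuple[int, int] | None = None) -> np.ndarray:
        if shape_hw is None:
            shape_hw = self.rois[0].mask.bits.shape
        lm = np.zeros(shape_hw, dtype=np.uint16)
        for r in self.rois:
            lm[r.mask.bits] = r.label
        return lm

    def get(self, label: int) -> ROI | None:
        for r in self.rois:
            if r.label == label:
                return r
        return None


# ---------------------------------------------------------------------------
# readers / writers

def read_thermal(path: str | Path, region: str, side: str,
                 scale: float = DEFAULT_TIFF_SCALE,
                 offset: float = DEFAULT_TIFF_OFFSET) -> ThermalImage:
    """Load a thermal matrix from CSV (already Celsius) or 16-bit TIFF.

    TIFF counts are converted via ``celsius = count * scale + offset``.
    Ragged CSV rows and non-finite cells are rejected with coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
        if raw.ndim != 2:
            raise ValueError(f"{path}: thermal TIFF must be single-channel")
        pixels = raw.astype(float) * scale + offset
    else:
        rows = []
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.reader(fh)):
                if not row:
                    continue
                try:
                    rows.append([float(x) for x in row])
                except ValueError as e:
                    raise ValueError(f"{path}: bad value in row {i}: {e}") from None
                if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                    raise ValueError(
                        f"{path}: ragged CSV — row {i} has {len(rows[-1])} "
                        f"cells, expected {len(rows[0])}")
        if not rows:
            raise ValueError(f"{path}: empty CSV")
        pixels = np.asarray(rows, dtype=float)
    return ThermalImage(pixels, region=region, side=side, source_path=str(path))


def write_thermal_csv(t: ThermalImage, path: str | Path) -> None:
    np.savetxt(path, t.pixels, delimiter=",", fmt="%.6g")


def read_visual(path: str | Path) -> VisualImage:
    """Load a PNG/JPEG/TIFF photograph; grayscale is replicated to RGB."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.uint8)
    return VisualImage(arr)


def write_visual(v: VisualImage, path: str | Path) -> None:
    Image.fromarray(v.pixels).save(path)


def write_mask_png(m: BinaryMask, path: str | Path) -> None:
    """Masks persist as 8-bit PNG, 255 = foreground."""
    Image.fromarray((m.bits * np.uint8(255))).save(path)


def read_mask_png(path: str | Path) -> BinaryMask:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return BinaryMask(arr >= 128)


def _shape_to_json(s: shp.Shape) -> dict:
    if isinstance(s, shp.Circle):
        return {"kind": "circle", "center": list(s.center), "radius": s.radius}
    if isinstance(s, shp.RotatedRect):
        return {"kind": "rotated_rect", "center": list(s.center),
                "width": s.width, "height": s.height, "angle": s.angle}
    if isinstance(s, shp.Quadrilateral):
        return {"kind": "quadrilateral",
                "vertices": [list(v) for v in s.vertices]}
    if isinstance(s, shp.Raster):
        return {"kind": "raster"}
    raise TypeError(type(s))


def _shape_from_json(d: dict, mask: np.ndarray) -> shp.Shape:
    k = d["kind"]
    if k == "circle":
        return shp.Circle(tuple(d["center"]), d["radius"])
    if k == "rotated_rect":
        return shp.RotatedRect(tuple(d["center"]), d["width"], d["height"],
                               d["angle"])
    if k == "quadrilateral":
        return shp.Quadrilateral(tuple(tuple(v) for v in d["vertices"]))
    if k == "raster":
        return shp.Raster(mask)
    raise ValueError(f"unknown shape kind {k!r}")


def write_roi_set(rs: ROISet, path: str | Path) -> None:
    """Write a ROISet as ``<path>`` (JSON) + ``<path stem>.tif`` label mask.

    Overlapping ROIs are rejected naming both labels.
    """
    overlaps = rs.overlapping_pairs()
    if overlaps:
        raise ValueError(f"refusing to write overlapping ROIs: {overlaps}")
    path = Path(path)
    tiff_path = path.with_suffix(".tif")
    doc = {
        "image_ref": rs.image_ref,
        "region": rs.region,
        "mask_shape": list(rs.rois[0].mask.bits.shape) if rs.rois else [0, 0],
        "label_mask": tiff_path.name,
        "rois": [
            {"label": r.label, "name": r.name, "shape": _shape_to_json(r.shape)}
            for r in rs.rois
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    if rs.rois:
        tifffile.imwrite(tiff_path, rs.label_mask())


def read_roi_set(path: str | Path) -> ROISet:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    tiff_path = path.parent / doc["label_mask"]
    if doc["rois"]:
        lm = tifffile.imread(tiff_path)
    else:
        lm = np.zeros(doc["mask_shape"], dtype=np.uint16)
    rois = []
    for rd in doc["rois"]:
        mask = lm == rd["label"]
        rois.append(ROI(label=rd["label"],
                        shape=_shape_from_json(rd["shape"], mask),
                        mask=BinaryMask(mask), name=rd["name"]))
    return ROISet(rois, image_ref=doc["image_ref"], region=doc["region"])


def extract_temperatures(t: ThermalImage, rs: ROISet) -> pd.DataFrame:
    """Per-ROI temperature summary: label, name, mean, SD, pixel count.

    The mean is the arithmetic mean over mask pixels; SD is the population
    standard deviation (ddof=0).
    """
    rows = []
    for r in rs.rois:
        if r.mask.bits.shape != t.pixels.shape:
            raise ValueError(
                f"ROI {r.name} mask {r.mask.bits.shape} does not match "
                f"image {t.pixels.shape}")
        vals = t.pixels[r.mask.bits]
        rows.append({
            "label": r.label,
            "name": r.name,
            "mean_temp": float(vals.mean()),
            "sd_temp": float(vals.std(ddof=0)),
            "pixel_count": int(vals.size),
        })
    return pd.DataFrame(rows, columns=["label", "name", "mean_temp",
                                       "sd_temp", "pixel_count"])
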