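"""Parametric region shapes and their rasterisation.

All coordinates are (row, col), 0-based, origin at the top-left pixel
center; larger row index means lower in the image.  A pixel belongs to a
shape iff its center lies inside or on the boundary of the shape.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

__all__ = [
    "Circle",
    "RotatedRect",
    "Quadrilateral",
    "Raster",
    "Shape",
    "rasterise",
    "transform_shape",
]


@dataclass(frozen=True)
class Circle:
    """Disc with center (row, col) and radius in pixels."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("circle radius must be positive")


@dataclass(frozen=True)
class RotatedRect:
    """Rectangle centered at ``center`` and rotated by ``angle`` degrees.

    ``width`` is the extent along the rectangle's local x axis, ``height``
    along its local y axis.  At angle 0 the local x axis is the image
    column axis and the local y axis is the image row axis.  Positive
    angles rotate the local x axis from +col toward +row.
    """

    center: tuple[float, float]
    width: float
    height: float
    angle: float = 0.0

    def vertices(self) -> np.ndarray:
        """Corner points, (4, 2) array of (row, col)."""
        th = np.deg2rad(self.angle)
        u = np.array([np.sin(th), np.cos(th)])   # width direction (row, col)
        v = np.array([np.cos(th), -np.sin(th)])  # height direction
        c = np.asarray(self.center, dtype=float)
        hw, hh = self.width / 2.0, self.height / 2.0
        return np.array([c - hw * u - hh * v,
                         c + hw * u - hh * v,
                         c + hw * u + hh * v,
                         c - hw * u + hh * v])


@dataclass(frozen=True)
class Quadrilateral:
    """Simple quadrilateral given by 4 vertices (row, col), in order."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.vertices) != 4:
            raise ValueError("quadrilateral needs exactly 4 vertices")

    def vertex_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


@dataclass(frozen=True)
class Raster:
    """Free-form region given directly by a boolean mask."""

    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


Shape = Circle | RotatedRect | Quadrilateral | Raster


def _polygon_raster(verts: np.ndarray, shape_hw: tuple[int, int]) -> np.ndarray:
    """Rasterise a convex/simple polygon: pixel centers covered by it."""
    h, w = shape_hw
    out = np.zeros((h, w), dtype=bool)
    r0 = max(int(np.floor(verts[:, 0].min())), 0)
    r1 = min(int(np.ceil(verts[:, 0].max())), h - 1)
    c0 = max(int(np.floor(verts[:, 1].min())), 0)
    c1 = min(int(np.ceil(verts[:, 1].max())), w - 1)
    if r1 < r0 or c1 < c0:
        return out
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    poly = shapely.Polygon(verts)
    pts = shapely.points(np.column_stack([rr.ravel(), cc.ravel()]))
    inside = shapely.covers(poly, pts).reshape(rr.shape)
    out[r0:r1 + 1, c0:c1 + 1] = inside
    return out


def rasterise(shape: Shape, shape_hw: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the pixels whose centers fall inside ``shape``.

    Pixels outside the ``shape_hw = (height, width)`` canvas are dropped.
    """
    h, w = shape_hw
    if isinstance(shape, Raster):
        m = shape.mask
        if m.shape != (h, w):
            out = np.zeros((h, w), dtype=bool)
            out[: min(h, m.shape[0]), : min(w, m.shape[1])] = \
                m[: min(h, m.shape[0]), : min(w, m.shape[1])]
            return out
        return m.copy()
    if isinstance(shape, Circle):
        (cr, cc0), rad = shape.center, shape.radius
        r0 = max(int(np.floor(cr - rad)), 0)
        r1 = min(int(np.ceil(cr + rad)), h - 1)
        c0 = max(int(np.floor(cc0 - rad)), 0)
        c1 = min(int(np.ceil(cc0 + rad)), w - 1)
        out = np.zeros((h, w), dtype=bool)
        if r1 < r0 or c1 < c0:
            return out
        rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        out[r0:r1 + 1, c0:c1 + 1] = \
            (rr - cr) ** 2 + (cc - cc0) ** 2 <= rad ** 2
        return out
    if isinstance(shape, RotatedRect):
        return _polygon_raster(shape.vertices(), shape_hw)
    if isinstance(shape, Quadrilateral):
        return _polygon_raster(shape.vertex_array(), shape_hw)
    raise TypeError(f"unknown shape type {type(shape)!r}")


def _is_similarity(lin: np.ndarray, tol: float = 1e-9) -> bool:
    g = lin.T @ lin
    s2 = 0.5 * (g[0, 0] + g[1, 1])
    return bool(abs(g[0, 1]) <= tol * max(s2, 1.0)
                and abs(g[0, 0] - g[1, 1]) <= tol * max(s2, 1.0))


def transform_shape(shape: Shape, matrix: np.ndarray) -> Shape:
    """Apply a 2x3 affine matrix (acting on (row, col, 1)) to a shape.

    Quadrilaterals transform exactly under any affinity.  Circles and
    rotated rectangles transform exactly only under similarities (rotation
    + uniform scale + translation); a non-similarity affine converts them
    to quadrilaterals (rects) or raises (circles).
    """
    matrix = np.asarray(matrix, dtype=float)
    lin, off = matrix[:, :2], matrix[:, 2]

    def apply(p):
        return lin @ np.asarray(p, dtype=float) + off

    if isinstance(shape, Quadrilateral):
        return Quadrilateral(tuple(tuple(apply(v)) for v in shape.vertices))
    if isinstance(shape, RotatedRect):
        if _is_similarity(lin):
            scale = float(np.sqrt(abs(np.linalg.det(lin))))
            dth = np.rad2deg(np.arctan2(lin[0, 1], lin[1, 1]))
            return RotatedRect(tuple(apply(shape.center)),
                               shape.width * scale, shape.height * scale,
                               shape.angle + dth)
        return transform_shape(Quadrilateral(tuple(map(tuple, shape.vertices()))),
                               matrix)
    if isinstance(shape, Circle):
        if not _is_similarity(lin):
            raise ValueError("circle under a non-similarity affine is not a circle")
        scale = float(np.sqrt(abs(np.linalg.det(lin))))
        return Circle(tuple(apply(shape.center)), shape.radius * scale)
    if isinstance(shape, Raster):
        raise ValueError("raster shapes cannot be transformed parametrically")
    raise TypeError(f"unknown shape type {type(shape)!r}")
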