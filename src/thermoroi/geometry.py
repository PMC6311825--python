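"""Planar geometry helpers shared by the pipelines and the phantoms.

The package-wide rotation convention: a positive angle theta rotates the
+col axis toward the +row axis, so ``rot_matrix(theta) @ (0, 1) ==
(sin(theta), cos(theta))``.  All matrices act on (row, col) column
vectors.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["rot_matrix", "rotation_about", "apply_affine", "invert_affine",
           "rotate_array", "compose_affine"]


def rot_matrix(angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, s], [-s, c]])


def rotation_about(angle_deg: float, center) -> np.ndarray:
    """2x3 affine rotating by ``angle_deg`` about ``center`` (row, col)."""
    lin = rot_matrix(angle_deg)
    ctr = np.asarray(center, dtype=float)
    off = ctr - lin @ ctr
    return np.hstack([lin, off[:, None]])


def apply_affine(matrix: np.ndarray, pts) -> np.ndarray:
    """Apply a 2x3 affine to an (N, 2) array (or single point) of (row, col)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    out = pts @ matrix[:, :2].T + matrix[:, 2]
    return out[0] if out.shape[0] == 1 else out


def invert_affine(matrix: np.ndarray) -> np.ndarray:
    lin = matrix[:, :2]
    inv = np.linalg.inv(lin)
    off = -inv @ matrix[:, 2]
    return np.hstack([inv, off[:, None]])


def compose_affine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Affine equal to applying b first, then a."""
    lin = a[:, :2] @ b[:, :2]
    off = a[:, :2] @ b[:, 2] + a[:, 2]
    return np.hstack([lin, off[:, None]])


def rotate_array(arr: np.ndarray, angle_deg: float, center=None,
                 order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Rotate an array by ``angle_deg`` about ``center`` keeping its shape.

    Output pixel o takes the value at input position R(-theta)(o - c) + c,
    i.e. the array content rotates by +theta under the package rotation
    convention.  Use order=0 for masks.
    """
    if center is None:
        center = ((arr.shape[0] - 1) / 2.0, (arr.shape[1] - 1) / 2.0)
    inv = rotation_about(-angle_deg, center)
    was_bool = arr.dtype == bool
    out = ndimage.affine_transform(
        arr.astype(float), inv[:, :2], offset=inv[:, 2], order=order,
        mode="constant", cval=cval)
    if was_bool:
        return out > 0.5
    return out
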