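"""Disc structuring elements and fast exact binary opening.

The disc SE of radius r contains offset (i, j) iff i^2 + j^2 <= r^2.
Opening with that SE is computed through two squared Euclidean distance
transforms, which is algebraically identical to erosion followed by
dilation with the rasterised disc (with background beyond the border,
i.e. border_value=0) but much faster for large radii:

  erosion(M, disc_r)  = { p : d^2(p, background or outside) >  r^2 }
  dilation(E, disc_r) = { p : d^2(p, E)                     <= r^2 }
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["disc_footprint", "binary_erosion_disc", "binary_opening_disc"]


def disc_footprint(r: int) -> np.ndarray:
    """Rasterised disc SE: (2r+1)^2 grid, True iff i^2+j^2 <= r^2."""
    if r < 0:
        raise ValueError("radius must be >= 0")
    ii, jj = np.mgrid[-r:r + 1, -r:r + 1]
    return ii * ii + jj * jj <= r * r


def _sq_dist_to(target: np.ndarray, outside_is_target: bool) -> np.ndarray:
    """Exact squared distance from every pixel to the nearest target pixel.

    A one-pixel pad stands in for the infinite plane beyond the border;
    the nearest outside pixel always lies in that first ring.  Distances
    are squared integers, re-rounded to kill sqrt round-off.
    """
    padded = np.pad(target, 1, constant_values=outside_is_target)
    d = ndimage.distance_transform_edt(~padded)[1:-1, 1:-1]
    return np.rint(d * d)


def binary_erosion_disc(mask: np.ndarray, r: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if r == 0:
        return mask.copy()
    d2 = _sq_dist_to(~mask, outside_is_target=True)
    return d2 > r * r


def binary_opening_disc(mask: np.ndarray, r: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if r == 0:
        return mask.copy()
    er = binary_erosion_disc(mask, r)
    if not er.any():
        return np.zeros_like(mask)
    d2 = _sq_dist_to(er, outside_is_target=False)
    return d2 <= r * r
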