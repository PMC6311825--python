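"""Foreground-background binarisation and mask hygiene.

Thermal images are binarised with local adaptive thresholding (a pixel is
foreground when it is warmer than the Gaussian-weighted mean of its
neighbourhood); visual images with Otsu's method on the 256-bin luminance
histogram.  ``clean_mask`` keeps the largest connected components and
fills small holes, the shared post-processing of every pipeline.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import resolve
from .thermal_io import BinaryMask, ThermalImage, VisualImage

__all__ = ["adaptive_threshold", "otsu_threshold", "otsu_scan", "clean_mask"]


def _window_side(h: int, w: int, fraction: float, measure: str) -> int:
    if measure == "linear":
        side = int(round(fraction * max(h, w)))
    elif measure == "area":
        side = int(round(np.sqrt(fraction * h * w)))
    else:
        raise ValueError(f"unknown neighborhood measure {measure!r}")
    if side % 2 == 0:
        side += 1
    return side


def adaptive_threshold(t: ThermalImage,
                       neighborhood_fraction: float | None = None,
                       offset: float = 0.0,
                       config: dict | None = None) -> BinaryMask:
    """Warmer-than-local-Gaussian-mean binarisation.

    The neighbourhood covers 1/16th of the image by default, read as an
    area fraction: window side = ``round(sqrt(fraction * H * W))`` forced
    odd (a linear reading, side = ``round(fraction * max(H, W))``, is
    selectable via the ``neighborhood_measure`` config key).  The
    Gaussian weight has ``sigma = window / 6`` and is truncated at the
    window half-side, with reflective (symmetric) border handling.

    ``offset`` is a sensitivity margin in degC: a pixel is foreground iff
    it exceeds the local mean by more than the offset.  The default 0
    makes ties background, so a constant image yields an empty mask; the
    pipelines pass the ``thermal_offset`` config default (0.1 degC, a few
    times a microbolometer's NETD) to keep sensor noise on a uniform
    background out of the mask.  Adding a constant to all temperatures
    never changes the result.
    """
    cfg = resolve(config)["segmentation"]
    frac = cfg["neighborhood_fraction"] if neighborhood_fraction is None \
        else neighborhood_fraction
    if not 0 < frac <= 1:
        raise ValueError("neighborhood_fraction must be in (0, 1]")
    side = _window_side(t.height, t.width, frac, cfg["neighborhood_measure"])
    if side < 3:
        raise ValueError(
            f"adaptive-threshold window is {side} px; use a larger "
            "neighborhood fraction or a larger image")
    sigma = side / cfg["sigma_divisor"]
    half = side // 2
    local_mean = ndimage.gaussian_filter(
        t.pixels, sigma=sigma, mode="reflect", truncate=half / sigma)
    return BinaryMask(t.pixels > local_mean + offset)


def otsu_scan(hist: np.ndarray) -> tuple[int, float]:
    """Exhaustive Otsu scan over a 256-bin histogram.

    Returns ``(threshold, best_variance)`` where the threshold t assigns
    bins <= t to class 0, maximising the between-class variance
    ``w0 * w1 * (mu0 - mu1)^2``.  Ties take the smallest t.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    levels = np.arange(hist.size, dtype=float)
    best_t, best_v = -1, -1.0
    for thr in range(hist.size - 1):
        w0 = hist[: thr + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[: thr + 1] * hist[: thr + 1]).sum() / w0
        mu1 = (levels[thr + 1:] * hist[thr + 1:]).sum() / w1
        v = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if v > best_v:
            best_t, best_v = thr, v
    return best_t, best_v


def otsu_threshold(v: VisualImage, bright_foreground: bool | None = None,
                   config: dict | None = None) -> BinaryMask:
    """Otsu binarisation of the luminance channel of a visual image.

    Foreground is the class containing the brighter mode unless
    ``bright_foreground`` (or the config key) flips the polarity.  A
    single-valued image has no separable classes and is rejected.
    """
    cfg = resolve(config)["segmentation"]
    if bright_foreground is None:
        bright_foreground = cfg["otsu_bright_foreground"]
    lum = np.clip(np.rint(v.luminance()), 0, 255).astype(np.uint8)
    if lum.min() == lum.max():
        raise ValueError("single-valued image: Otsu has no separable classes")
    hist = np.bincount(lum.ravel(), minlength=256)
    thr, _ = otsu_scan(hist)
    fg = lum > thr
    if not bright_foreground:
        fg = ~fg
    return BinaryMask(fg)


def clean_mask(m: BinaryMask, k: int = 1, min_area: int | None = None,
               config: dict | None = None) -> BinaryMask:
    """Keep the k largest 8-connected components and fill small holes.

    Components below ``min_area`` pixels are discarded even when fewer
    than k survive; background cavities (4-connected, not touching the
    border) smaller than ``min_area`` are filled.  Idempotent.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cfg = resolve(config)["segmentation"]
    if min_area is None:
        min_area = cfg["min_area"]
    bits = m.bits
    if not bits.any():
        raise ValueError("no foreground found")
    lab, n = ndimage.label(bits, structure=np.ones((3, 3), dtype=bool))
    areas = np.bincount(lab.ravel())[1:]
    order = np.argsort(areas, kind="stable")[::-1]
    keep = [i + 1 for i in order[:k] if areas[i] >= min_area]
    out = np.isin(lab, keep)
    if not out.any():
        raise ValueError("no foreground found after cleaning")
    # fill holes smaller than min_area (4-connected background cavities)
    hole_lab, hn = ndimage.label(~out)
    border = np.unique(np.concatenate([
        hole_lab[0, :], hole_lab[-1, :], hole_lab[:, 0], hole_lab[:, -1]]))
    hole_areas = np.bincount(hole_lab.ravel())
    for h in range(1, hn + 1):
        if h in border:
            continue
        if hole_areas[h] < min_area:
            out[hole_lab == h] = True
    return BinaryMask(out)
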