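"""Numeric defaults for every pipeline, overridable from YAML.

Keys are namespaced per module.  ``load_config`` deep-merges a user YAML
file over the defaults; pipelines accept the merged dict (or ``None`` for
pure defaults).
"""
from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "io": {
        "tiff_scale": 0.01,
        "tiff_offset": 0.0,
    },
    "segmentation": {
        "neighborhood_fraction": 1.0 / 16.0,  # of the image area
        "neighborhood_measure": "area",        # or "linear" (of max(H, W))
        "sigma_divisor": 6.0,                  # gaussian sigma = window / 6
        "thermal_offset": 0.1,  # degC sensitivity margin over the local mean
        "min_area": 100,                       # clean_mask component floor / hole fill
        "otsu_bright_foreground": True,
    },
    "hand": {
        "variance_window": 5,      # N of the moving-window variance detector
        "variance_factor": 20.0,    # exceedance factor over the reference
        "min_finger_area": 30,
        "hough_radius_frac": (0.25, 0.6),  # of finger minor-axis width
    },
    "shin": {
        "width_frac": 0.6,    # ROI width as fraction of local shin width
        "height_frac": 0.12,  # ROI height as fraction of medial-line length
        "min_rows": 10,
        "orientation": "viewer",  # smaller centroid column = right shin
    },
    "foot": {
        "log_sigma": 2.0,
        "edge_min_len": 10,
        "edge_min_intensity": 5.0,   # mean |LoG| (0-255 luma units)
        "toe_open_radius": 3,
        "beta": 0.3,                 # circle diameter fraction of foot width
        "alpha": 0.25,               # quadrilateral width fraction
        "tau_frac": 0.35,            # tau as fraction of foot length
        "heel_hough_diam_frac": (0.5, 1.0),  # of median foot width
        "sobel_percentile": 90.0,
        "min_quad_area_frac": 0.25,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, over: dict) -> dict:
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path: str | Path | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _merge(cfg, user)
    return cfg


def resolve(cfg: dict | None) -> dict:
    """Merge a partial override dict over the defaults (``None`` -> defaults)."""
    if cfg is None:
        return default_config()
    return _merge(default_config(), copy.deepcopy(cfg))
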