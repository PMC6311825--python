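"""Extraction of the 6 shin regions: 3 rotated rectangles per shin.

Each segmented shin yields a medial line (per-row run midpoints), whose
least-squares fit gives the limb orientation.  Reference points at
arc-length fractions {top inset, 1/2, 3/4} of the medial line anchor
rectangular ROIs scaled to the local limb width and rotated to follow
the limb.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import shapes as shp
from .config import resolve
from .labels import NAME_TO_LABEL, SHIN_PARTS
from .reporting import ExtractionResult, PipelineReport
from .segmentation import adaptive_threshold, clean_mask
from .thermal_io import ROI, BinaryMask, ROISet, ThermalImage

__all__ = ["MedialLine", "medial_line", "shin_reference_points",
           "place_shin_rects", "extract_shin_rois"]


@dataclass(frozen=True)
class MedialLine:
    """Ordered midpoints of a limb mask, top of the shin downward."""

    points: np.ndarray   # (n, 2) of (row, col), increasing row
    angle: float         # degrees vs the image horizontal axis, in (0, 180)
    length: float        # polyline arc length, px

    def __post_init__(self):
        object.__setattr__(self, "points",
                           np.asarray(self.points, dtype=float))
        if not 0.0 < self.angle < 180.0:
            raise ValueError("angle must lie in (0, 180) degrees")


def _longest_run(row_bits: np.ndarray) -> tuple[int, int] | None:
    """(first, last) columns of the longest foreground run in a row."""
    idx = np.flatnonzero(row_bits)
    if idx.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    lengths = idx[ends] - idx[starts]
    k = int(np.argmax(lengths))
    return int(idx[starts[k]]), int(idx[ends[k]])


def medial_line(shin_mask: BinaryMask, min_rows: int = 10) -> MedialLine:
    """Per-row midline of a single-component limb mask plus its angle.

    Midpoints come from the longest foreground run per row (so they stay
    inside the mask even for concave shapes); the angle is that of the
    least-squares line col = a*row + b, measured against the horizontal
    axis of the image.
    """
    bits = shin_mask.bits
    rows = np.flatnonzero(bits.any(axis=1))
    if rows.size < min_rows:
        raise ValueError(f"mask spans {rows.size} rows; need >= {min_rows}")
    pts, run_lens = [], []
    for r in rows:
        run = _longest_run(bits[r])
        first, last = run
        pts.append((float(r), (first + last) / 2.0))
        run_lens.append(last - first + 1)
    pts = np.asarray(pts)
    run_lens = np.asarray(run_lens, dtype=float)
    # rows clipped by the limb's end corners have short runs whose
    # midpoints sit off the axis; exclude them from the orientation fit
    full = run_lens >= 0.7 * np.median(run_lens)
    fit_pts = pts[full] if full.sum() >= min_rows else pts
    a = np.polyfit(fit_pts[:, 0], fit_pts[:, 1], 1)[0]  # d col / d row
    angle = float(np.degrees(np.arctan2(1.0, a)))
    seg = np.diff(pts, axis=0)
    length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return MedialLine(pts, angle, length)


def _point_at_arclength(points: np.ndarray, s: float) -> np.ndarray:
    seg = np.diff(points, axis=0)
    d = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(d)])
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(d) - 1)
    t = 0.0 if d[i] == 0 else (s - cum[i]) / d[i]
    return points[i] + t * seg[i]


def shin_reference_points(ml: MedialLine, height_frac: float = 0.12
                          ) -> np.ndarray:
    """Anchor points at arc-length fractions {inset, 1/2, 3/4} of the line.

    The top point is inset by half the ROI height (height_frac * length /
    2) so the top rectangle fits inside the limb.
    """
    inset = 0.5 * height_frac * ml.length
    fracs = [inset, 0.5 * ml.length, 0.75 * ml.length]
    return np.asarray([_point_at_arclength(ml.points, s) for s in fracs])


def place_shin_rects(pts: np.ndarray, ml: MedialLine, shin_mask: BinaryMask,
                     width_frac: float = 0.6, height_frac: float = 0.12,
                     ) -> list[tuple[shp.RotatedRect, np.ndarray, list[str]]]:
    """Rotated rectangles centered on the reference points.

    Width = width_frac x the local limb width at the point's row; height
    = height_frac x the medial-line length; the width axis runs
    perpendicular to the medial line.  Rectangles whose rasterisation
    leaks more than 1% outside the mask are shrunk stepwise (warned);
    the final mask is always clipped to the limb.
    """
    bits = shin_mask.bits
    th = np.deg2rad(ml.angle)
    d = np.array([np.sin(th), np.cos(th)])          # along-limb direction
    u = np.array([-d[1], d[0]])                      # across-limb direction
    rect_angle = float(np.degrees(np.arctan2(u[0], u[1])))
    out = []
    for p in np.atleast_2d(pts):
        r = int(round(p[0]))
        run = _longest_run(bits[np.clip(r, 0, bits.shape[0] - 1)])
        if run is None:
            raise ValueError(f"reference point row {r} has no foreground")
        local_w = run[1] - run[0] + 1
        width = width_frac * local_w
        height = height_frac * ml.length
        rect = shp.RotatedRect((float(p[0]), float(p[1])), width, height,
                               rect_angle)
        warnings: list[str] = []
        for _ in range(30):
            raster = shp.rasterise(rect, bits.shape)
            area = raster.sum()
            outside = (raster & ~bits).sum()
            if area == 0 or outside / max(area, 1) <= 0.01:
                break
            rect = shp.RotatedRect(rect.center, rect.width * 0.97,
                                   rect.height * 0.97, rect.angle)
            if not warnings:
                warnings.append(
                    f"rect at {tuple(np.round(p, 1))} shrunk to fit the limb")
        raster = shp.rasterise(rect, bits.shape) & bits
        out.append((rect, raster, warnings))
    return out


def extract_shin_rois(t: ThermalImage, config: dict | None = None
                      ) -> ExtractionResult:
    """Full shin cascade on an image containing (up to) both shins."""
    cfg = resolve(config)
    shin_cfg = cfg["shin"]
    if t.region != "shin":
        raise ValueError("image region must be 'shin'")
    report = PipelineReport(region="shin")
    empty = ROISet([], image_ref=t.source_path, region="shin")
    all_labels = [NAME_TO_LABEL[f"{p}_{s}"] for s in ("R", "L")
                  for p in SHIN_PARTS]

    try:
        mask = adaptive_threshold(
            t, offset=cfg["segmentation"]["thermal_offset"], config=cfg)
        mask = clean_mask(mask, k=2, config=cfg)
        report.record("segmentation", True)
    except ValueError as e:
        report.record("segmentation", False, str(e))
        report.missing_labels = all_labels
        return ExtractionResult(empty, report)

    lab, nlab = ndimage.label(mask.bits, structure=np.ones((3, 3), bool))
    comps = []
    for i in range(1, nlab + 1):
        m = lab == i
        comps.append((np.argwhere(m)[:, 1].mean(), m))
    comps.sort(key=lambda t_: t_[0])
    if nlab < 2:
        report.warn(f"found {nlab} shin component(s); expected 2")
    if nlab == 0:
        report.record("components", False, "no shin components")
        report.missing_labels = all_labels
        return ExtractionResult(empty, report)
    report.record("components", True, f"{nlab} component(s)")

    # viewer orientation (default): smaller centroid column = right shin
    if nlab >= 2:
        sides = ["R", "L"]
        use = comps[:2]
    else:
        col = comps[0][0]
        sides = ["R" if col < mask.width / 2 else "L"]
        use = comps

    rois: list[ROI] = []
    for side_tag, (_, comp) in zip(sides, use):
        try:
            ml = medial_line(BinaryMask(comp), shin_cfg["min_rows"])
            pts = shin_reference_points(ml, shin_cfg["height_frac"])
            placed = place_shin_rects(pts, ml, BinaryMask(comp),
                                      shin_cfg["width_frac"],
                                      shin_cfg["height_frac"])
        except ValueError as e:
            report.record(f"medial_line_{side_tag}", False, str(e))
            report.missing_labels += [NAME_TO_LABEL[f"{p}_{side_tag}"]
                                      for p in SHIN_PARTS]
            continue
        report.record(f"medial_line_{side_tag}", True,
                      f"angle={ml.angle:.1f}")
        taken = np.zeros_like(comp)
        for part, (rect, raster, warns) in zip(SHIN_PARTS, placed):
            labno = NAME_TO_LABEL[f"{part}_{side_tag}"]
            for w in warns:
                report.warn(w)
            m = raster & ~taken
            if not m.any():
                report.missing_labels.append(labno)
                continue
            taken |= m
            rois.append(ROI(label=labno, shape=rect, mask=BinaryMask(m)))

    rs = ROISet(rois, image_ref=t.source_path, region="shin")
    return ExtractionResult(rs, report, foreground=mask)
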