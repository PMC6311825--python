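"""Extraction of the 11 per-foot regions from a thermal + visual pair.

Foot skin is often near background temperature, so the thermal image
cannot be segmented reliably on its own.  The co-acquired visual image,
registered onto the thermal grid through a user-supplied >= 3-point
affine, is binarised with Otsu's method instead; the mask is then
rotated so the foot's principal axis is vertical (toes up).

Toes: a Laplacian-of-Gaussian edge map of the upper half of the aligned
visual image is skeletonised, stripped of the outer foot contour and of
short/weak chains, re-joined at endpoint edgels, and closed regions are
flood-filled; the five largest are the toes, shaped by a disc opening.

Ball of the foot and heel: a circle of diameter beta * W_r (W_r = foot
width at row r) centered on the per-row width midpoint c(W_r) slides up
from the bottom row until its center reaches Euclidean distance tau from
the toe reference point; two quadrilaterals of width alpha * W_r* are
centered at

    Q1c = (Cx - beta W_r*/2 - W_rect/4, r*),
    Q2c = (Cx + beta W_r*/2 + W_rect/4, r*),

then nudged off toes (top edge down) and background (outer vertices
diagonally inward).  The heel repeats the construction with r* taken
from the lowest-centered circle-Hough candidate on the thermal edge map.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import skeletonize
from skimage.transform import hough_circle, hough_circle_peaks

from . import shapes as shp
from .config import resolve
from .geometry import invert_affine, rot_matrix, rotate_array, rotation_about
from .labels import NAME_TO_LABEL, TOES
from .reporting import ExtractionResult, PipelineReport
from .segmentation import clean_mask, otsu_threshold
from .thermal_io import (ROI, BinaryMask, ROISet, ThermalImage, VisualImage)

__all__ = [
    "AffineTransform", "WidthProfile", "PlacementParams", "ToeRowRef",
    "register_visual_to_thermal", "warp_visual", "align_foot_vertical",
    "width_profile", "toe_edge_map", "filter_spurious_edges",
    "link_edge_endpoints", "toe_regions", "bof_circle", "place_quads",
    "heel_circle", "extract_foot_rois",
]


# ---------------------------------------------------------------------------
# registration

@dataclass(frozen=True)
class AffineTransform:
    """2x3 matrix mapping visual (row, col, 1) to thermal (row, col)."""

    matrix: np.ndarray
    max_residual: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) <= 1e-9:
            raise ValueError("singular linear part")

    def apply(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = pts @ self.matrix[:, :2].T + self.matrix[:, 2]
        return out[0] if out.shape[0] == 1 else out

    def inverse(self) -> "AffineTransform":
        return AffineTransform(invert_affine(self.matrix))


def register_visual_to_thermal(vis_pts, therm_pts) -> AffineTransform:
    """Affine from >= 3 corresponding (row, col) point pairs.

    Exactly 3 points give the exact linear solve; more give the least
    squares fit.  The maximum point residual is recorded on the result.
    """
    vis = np.atleast_2d(np.asarray(vis_pts, dtype=float))
    therm = np.atleast_2d(np.asarray(therm_pts, dtype=float))
    if vis.shape != therm.shape or vis.shape[0] < 3:
        raise ValueError("need equal counts of >= 3 corresponding points")
    if len(np.unique(vis.round(9), axis=0)) < vis.shape[0]:
        raise ValueError("duplicate points")
    A = np.hstack([vis, np.ones((vis.shape[0], 1))])
    if np.linalg.matrix_rank(A, tol=1e-7) < 3:
        raise ValueError("collinear points: affine underdetermined")
    sol, *_ = np.linalg.lstsq(A, therm, rcond=None)
    matrix = sol.T
    resid = np.abs(A @ sol - therm).max()
    return AffineTransform(matrix, float(resid))


def warp_visual(v: VisualImage, T: AffineTransform,
                shape_hw: tuple[int, int]) -> VisualImage:
    """Resample the visual image onto the thermal grid (inverse-mapped
    bilinear interpolation; pixels mapping outside the source are black).
    """
    inv = invert_affine(T.matrix)
    out = np.empty(shape_hw + (3,), dtype=np.uint8)
    for ch in range(3):
        w = ndimage.affine_transform(
            v.pixels[..., ch].astype(float), inv[:, :2], offset=inv[:, 2],
            output_shape=shape_hw, order=1, mode="constant", cval=0.0)
        out[..., ch] = np.clip(np.rint(w), 0, 255).astype(np.uint8)
    return VisualImage(out)


# ---------------------------------------------------------------------------
# vertical alignment

def _halfwidth_means(bits: np.ndarray) -> tuple[float, float]:
    rows = np.flatnonzero(bits.any(axis=1))
    counts = bits[rows].sum(axis=1).astype(float)
    mid = len(rows) // 2
    return counts[:mid].mean(), counts[mid:].mean()


def align_foot_vertical(m: BinaryMask) -> tuple[BinaryMask, float]:
    """Rotate the mask so its principal axis is vertical, toes up.

    The dominant eigenvector of the foreground-coordinate covariance is
    mapped to the row axis; the 180-degree ambiguity is resolved by
    putting the narrower half of the (pixel-count) width profile at the
    top.  Returns (rotated mask, applied rotation in degrees).
    """
    pts = np.argwhere(m.bits).astype(float)
    if pts.shape[0] < 2:
        raise ValueError("mask too small to orient")
    cov = np.cov((pts - pts.mean(axis=0)).T)
    w, vecs = np.linalg.eigh(cov)
    if w[1] / max(w[0], 1e-12) < 1.05:
        raise ValueError("no dominant axis (mask is near isotropic)")
    v = vecs[:, 1]
    rotation = float(np.degrees(np.arctan2(v[1], v[0])))
    if rotation > 90:
        rotation -= 180
    elif rotation <= -90:
        rotation += 180
    rotated = rotate_array(m.bits, rotation, order=0)
    top, bottom = _halfwidth_means(rotated)
    if top > bottom:
        rotation += 180.0
        rotated = rotate_array(m.bits, rotation, order=0)
    return BinaryMask(rotated), rotation


# ---------------------------------------------------------------------------
# width profile and placement types

@dataclass(frozen=True)
class WidthProfile:
    """Per-row foot width W_r (horizontal span) and its midpoint c(W_r)."""

    rows: np.ndarray
    widths: np.ndarray
    centers: np.ndarray

    def at(self, row: int) -> tuple[float, float]:
        i = np.searchsorted(self.rows, row)
        if i >= len(self.rows) or self.rows[i] != row:
            raise KeyError(f"row {row} has no foreground")
        return float(self.widths[i]), float(self.centers[i])


def width_profile(m: BinaryMask) -> WidthProfile:
    rows_, widths, centers = [], [], []
    for r in np.flatnonzero(m.bits.any(axis=1)):
        idx = np.flatnonzero(m.bits[r])
        rows_.append(r)
        widths.append(idx[-1] - idx[0] + 1)
        centers.append((idx[0] + idx[-1]) / 2.0)
    return WidthProfile(np.asarray(rows_), np.asarray(widths, float),
                        np.asarray(centers, float))


@dataclass(frozen=True)
class PlacementParams:
    """Geometry of the circular + quadrilateral deep-foot ROIs.

    beta: circle diameter as a fraction of the foot width at its row.
    tau: target distance (px) between circle center and toe reference.
    alpha: quadrilateral width as a fraction of the foot width at r*.
    """

    beta: float = 0.3
    tau: float = 60.0
    alpha: float = 0.25

    def __post_init__(self):
        if not (0 < self.beta < 1 and 0 < self.alpha < 1 and self.tau > 0):
            raise ValueError("need beta, alpha in (0,1) and tau > 0")


@dataclass(frozen=True)
class ToeRowRef:
    """Reference point of the toe ROI block: middle row R + column."""

    row: float
    col: float


# ---------------------------------------------------------------------------
# toe machinery

def _log_response(v: VisualImage, sigma: float) -> np.ndarray:
    return ndimage.gaussian_laplace(v.luminance(), sigma=sigma)


def _outer_contour(bits: np.ndarray) -> np.ndarray:
    er = ndimage.binary_erosion(bits, np.ones((3, 3), bool), border_value=0)
    return bits & ~er


def toe_edge_map(v_aligned: VisualImage, foot_mask: BinaryMask,
                 sigma: float = 2.0, zc_eps: float = 0.5) -> BinaryMask:
    """Skeletonised LoG zero-crossing edges of the upper half of the foot,
    with the outer foot contour removed.

    A pixel is a zero crossing when its LoG response differs in sign from
    a 4-neighbour and the jump magnitude exceeds ``zc_eps`` (suppresses
    sign flicker of the flat response over smooth shading).
    """
    bits = foot_mask.bits
    rows = np.flatnonzero(bits.any(axis=1))
    if rows.size == 0:
        raise ValueError("empty foot mask")
    top, bottom = rows[0], rows[-1]
    mid = (top + bottom) // 2
    log = _log_response(v_aligned, sigma)
    zc = np.zeros_like(bits)
    for ax, shift in ((0, 1), (1, 1)):
        a = log
        b = np.roll(log, shift, axis=ax)
        cross = (np.sign(a) != np.sign(b)) & (np.abs(a - b) > zc_eps)
        cross &= np.abs(a) <= np.abs(b)   # keep the smaller-magnitude side
        zc |= cross
        b2 = np.roll(log, -shift, axis=ax)
        cross2 = (np.sign(a) != np.sign(b2)) & (np.abs(a - b2) > zc_eps)
        cross2 &= np.abs(a) <= np.abs(b2)
        zc |= cross2
    region = np.zeros_like(bits)
    region[top:mid + 1] = True
    zc &= region & ndimage.binary_dilation(bits, np.ones((3, 3), bool))
    if not zc.any():
        return BinaryMask(zc)
    sk = skeletonize(zc)
    contour_band = ndimage.binary_dilation(_outer_contour(bits),
                                           np.ones((5, 5), bool))
    sk &= ~contour_band
    return BinaryMask(sk)


def filter_spurious_edges(edges: BinaryMask, v_aligned: VisualImage,
                          min_len: int = 10, min_intensity: float = 5.0,
                          sigma: float = 2.0) -> BinaryMask:
    """Drop edge chains that are short or weak.

    A chain survives when its pixel count >= min_len and its mean edge
    strength >= min_intensity (illumination streaks and shadow edges are
    weaker than the skin creases around the toes).  Strength is the local
    peak |LoG| response around each edgel — the response at a zero
    crossing itself is near zero, so the flanking lobe amplitude is what
    separates strong from weak edges.
    """
    log_mag = ndimage.maximum_filter(
        np.abs(_log_response(v_aligned, sigma)), size=5)
    lab, nlab = ndimage.label(edges.bits, structure=np.ones((3, 3), bool))
    out = np.zeros_like(edges.bits)
    for i in range(1, nlab + 1):
        chain = lab == i
        if chain.sum() < min_len:
            continue
        if log_mag[chain].mean() < min_intensity:
            continue
        out |= chain
    return BinaryMask(out)


def _neighbor_count(bits: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(bits.astype(int), k, mode="constant")


def link_edge_endpoints(edges: BinaryMask, outer_contour: BinaryMask
                        ) -> BinaryMask:
    """Join endpoint edgels to the nearest edgel on a different contour
    and flood-fill the resulting closed areas.

    The outer contour is restored (unioned) before linking.  An endpoint
    is a pixel with exactly one 8-neighbour on the combined map; its link
    target is the closest edgel belonging to a different connected chain,
    ties broken by lexicographic (row, col).  Returns the union of all
    enclosed areas (regions not reachable from the array border).
    """
    combined = edges.bits | outer_contour.bits
    if not combined.any():
        return BinaryMask(np.zeros_like(combined))
    lab, _ = ndimage.label(combined, structure=np.ones((3, 3), bool))
    nbr = _neighbor_count(combined)
    endpoints = np.argwhere(combined & (nbr == 1))
    all_pts = np.argwhere(combined)
    linked = combined.copy()
    for ep in endpoints:
        own = lab[ep[0], ep[1]]
        other = all_pts[lab[all_pts[:, 0], all_pts[:, 1]] != own]
        if other.size == 0:
            continue
        d = np.hypot(other[:, 0] - ep[0], other[:, 1] - ep[1])
        dmin = d.min()
        cand = other[d <= dmin + 1e-9]
        cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
        tgt = cand[0]
        rr, cc = draw_line(int(ep[0]), int(ep[1]), int(tgt[0]), int(tgt[1]))
        linked[rr, cc] = True
    filled = ndimage.binary_fill_holes(linked)
    return BinaryMask(filled & ~linked)


def toe_regions(closed: BinaryMask, open_radius: int = 3, side: str = "right",
                min_area: int = 20
                ) -> tuple[list[tuple[str, np.ndarray]], list[str]]:
    """Pick the five largest closed regions as toes and shape them.

    Each kept region is opened with a disc SE of ``open_radius``.  Toes
    are ordered by centroid column and named toe_1..toe_5 with toe_1 the
    hallux: leftmost column for a right foot, rightmost for a left foot.
    Returns (name, mask) pairs plus messages for missing toes.
    """
    from .morpho import binary_opening_disc
    # 4-connected labelling: regions bounded by 1-px (8-connected) edge
    # chains are only separated under the dual connectivity
    lab, nlab = ndimage.label(closed.bits)
    areas = np.bincount(lab.ravel())[1:]
    order = [i + 1 for i in np.argsort(areas, kind="stable")[::-1]
             if areas[i] >= min_area][:5]
    messages = []
    if len(order) < 5:
        messages.append(f"only {len(order)} closed toe regions found")
    regions = []
    for i in order:
        m = binary_opening_disc(lab == i, open_radius)
        if not m.any():
            messages.append("toe candidate vanished under opening")
            continue
        regions.append((np.argwhere(m)[:, 1].mean(), m))
    regions.sort(key=lambda t: t[0])
    if side == "left":
        regions = regions[::-1]
    named = [(TOES[k], m) for k, (_, m) in enumerate(regions)]
    return named, messages


# ---------------------------------------------------------------------------
# circle + quadrilateral placement

def bof_circle(wp: WidthProfile, toe_ref: ToeRowRef, params: PlacementParams
               ) -> shp.Circle:
    """Slide the width-scaled circle up from the bottom row to distance tau.

    At each row r the candidate circle is centered at (r, c(W_r)) with
    diameter beta * W_r; the scan stops at the first row r* (moving
    upward) where the Euclidean distance between the center and the toe
    reference point drops to tau or below.
    """
    for i in range(len(wp.rows) - 1, -1, -1):
        r = int(wp.rows[i])
        w, c = wp.widths[i], wp.centers[i]
        if w <= 0:
            continue
        d = np.hypot(r - toe_ref.row, c - toe_ref.col)
        if d <= params.tau:
            return shp.Circle((float(r), float(c)), params.beta * w / 2.0)
    raise ValueError("circle scan exhausted all rows without reaching tau")


@dataclass(frozen=True)
class QuadPair:
    q1: shp.Quadrilateral | None
    q2: shp.Quadrilateral | None
    missing: tuple[str, ...] = ()


def _initial_quad(center: tuple[float, float], side_len: float
                  ) -> np.ndarray:
    """Vertices A, B, C, D of an axis-aligned square; A and B are the two
    top vertices, with A on the outer side (assigned by the caller)."""
    r, c = center
    h = side_len / 2.0
    return np.array([[r - h, c - h], [r - h, c + h],
                     [r + h, c + h], [r + h, c - h]])


def _adjust_quad(verts: np.ndarray, outer_is_left: bool,
                 toe_bits: np.ndarray, foot_bits: np.ndarray,
                 min_area: float, max_steps: int = 400
                 ) -> np.ndarray | None:
    """Nudge a quad off toe ROIs (top edge down) and background (outer
    vertices diagonally toward the center), per 1-px steps."""
    v = verts.copy()
    hw = foot_bits.shape
    # vertex indices: 0=A (top outer), 1=B (top inner), 2=C, 3=D (bottom outer)
    if outer_is_left:
        ia, ib, ic, id_ = 0, 1, 2, 3
    else:
        ia, ib, ic, id_ = 1, 0, 3, 2
    for _ in range(max_steps):
        quad = shp.Quadrilateral(tuple(map(tuple, v)))
        raster = shp.rasterise(quad, hw)
        area = raster.sum()
        if area == 0 or _poly_area(v) < min_area:
            return None
        if (raster & toe_bits).any():
            v[ia, 0] += 1.0
            v[ib, 0] += 1.0
            continue
        if (raster & ~foot_bits).any():
            ctr = v.mean(axis=0)
            for k in (ia, id_):
                v[k] += np.sign(ctr - v[k])
            continue
        return v
    return None


def _poly_area(v: np.ndarray) -> float:
    x, y = v[:, 1], v[:, 0]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def place_quads(circ: shp.Circle, wp: WidthProfile, params: PlacementParams,
                toe_masks: list[np.ndarray], foot_mask: BinaryMask,
                min_quad_area_frac: float = 0.25) -> QuadPair:
    """The two quadrilaterals flanking a placed circle.

    Centers follow the closed-form offsets +-(beta W_r*/2 + W_rect/4)
    from the circle center column at row r*; the initial shape is an
    axis-aligned square of side W_rect = alpha W_r*.  Overlap with toe
    ROIs moves the top edge down; overlap with background moves the
    outer vertices diagonally inward; shrinkage below
    ``min_quad_area_frac`` of the initial area reports the quad missing.
    """
    r_star = int(round(circ.center[0]))
    w_star, _ = wp.at(r_star)
    cx = circ.center[1]
    w_rect = params.alpha * w_star
    off = params.beta * w_star / 2.0 + w_rect / 4.0
    toe_bits = np.zeros_like(foot_mask.bits)
    for m in toe_masks:
        toe_bits |= m
    min_area = min_quad_area_frac * w_rect * w_rect
    quads, missing = [], []
    for name, col, outer_left in (("q1", cx - off, True),
                                  ("q2", cx + off, False)):
        v0 = _initial_quad((float(r_star), float(col)), w_rect)
        v = _adjust_quad(v0, outer_left, toe_bits, foot_mask.bits, min_area)
        if v is None:
            quads.append(None)
            missing.append(name)
        else:
            quads.append(shp.Quadrilateral(tuple(map(tuple, v))))
    return QuadPair(quads[0], quads[1], tuple(missing))


def quad_centers(w_star: float, cx: float, params: PlacementParams
                 ) -> tuple[float, float]:
    """Closed-form quadrilateral center columns at r* (for validation)."""
    w_rect = params.alpha * w_star
    off = params.beta * w_star / 2.0 + w_rect / 4.0
    return cx - off, cx + off


def heel_circle(t_aligned: ThermalImage, foot_mask: BinaryMask,
                params: PlacementParams, diam_frac=(0.5, 1.0),
                sobel_percentile: float = 90.0) -> shp.Circle:
    """Heel circle seeded by the lowest circle-Hough candidate.

    The Hough transform runs on the thermal gradient-magnitude edge map
    (Sobel, thresholded at ``sobel_percentile`` inside the mask) over
    diameters ``diam_frac`` x the median foot width; the candidate whose
    center sits lowest (largest row) anchors the heel, and its row seeds
    the same width-scaled circle construction as the ball of the foot.
    """
    bits = foot_mask.bits
    gr = ndimage.sobel(t_aligned.pixels, axis=0)
    gc = ndimage.sobel(t_aligned.pixels, axis=1)
    mag = np.hypot(gr, gc)
    band = ndimage.binary_dilation(bits, np.ones((5, 5), bool))
    vals = mag[band]
    if vals.size == 0 or vals.max() <= 0:
        raise ValueError("edge-free thermal image: no heel candidates")
    thr = np.percentile(vals, sobel_percentile)
    edges = (mag >= thr) & band
    wp = width_profile(foot_mask)
    med_w = float(np.median(wp.widths))
    radii = np.arange(max(2, int(diam_frac[0] * med_w / 2)),
                      max(3, int(diam_frac[1] * med_w / 2)) + 1)
    acc = hough_circle(edges, radii)
    accums, cols, rows, rads = hough_circle_peaks(
        acc, radii, total_num_peaks=10, normalize=True)
    if len(rows) == 0:
        raise ValueError("no heel circle candidate found")
    # only well-supported circles count as candidates; among those the
    # lowest-centered one is the heel
    floor = 0.5 * max(accums)
    keep = [i for i in range(len(rows)) if accums[i] >= floor]
    best = max(keep, key=lambda i: (rows[i], rads[i]))
    anchor_row = int(rows[best])
    w, c = wp.at(int(np.clip(anchor_row, wp.rows[0], wp.rows[-1])))
    return shp.Circle((float(anchor_row), c), params.beta * w / 2.0)


# ---------------------------------------------------------------------------
# full cascade

def _backmap_shape(s: shp.Shape, rotation: float, center) -> shp.Shape:
    if rotation == 0.0:
        return s
    inv = rotation_about(-rotation, center)
    return shp.transform_shape(s, inv)


def extract_foot_rois(t: ThermalImage, v: VisualImage, vis_pts, therm_pts,
                      config: dict | None = None) -> ExtractionResult:
    """Full foot cascade from a thermal/visual pair plus landmarks."""
    cfg = resolve(config)
    fc = cfg["foot"]
    if t.region != "foot":
        raise ValueError("image region must be 'foot'")
    if t.side not in ("left", "right"):
        raise ValueError("foot side must be 'left' or 'right'")
    side_tag = "R" if t.side == "right" else "L"
    toe_labels = [NAME_TO_LABEL[f"{n}_{side_tag}"] for n in TOES]
    deep_parts = ("bof_circle", "bof_quad_1", "bof_quad_2",
                  "heel_circle", "heel_quad_1", "heel_quad_2")
    deep_labels = [NAME_TO_LABEL[f"{p}_{side_tag}"] for p in deep_parts]
    report = PipelineReport(region="foot")
    empty = ROISet([], image_ref=t.source_path, region="foot")

    try:
        T = register_visual_to_thermal(vis_pts, therm_pts)
        report.record("registration", True,
                      f"max_residual={T.max_residual:.3g}")
    except ValueError as e:
        report.record("registration", False, str(e))
        report.missing_labels = toe_labels + deep_labels
        return ExtractionResult(empty, report)

    try:
        v_reg = warp_visual(v, T, t.pixels.shape)
        mask = otsu_threshold(v_reg, config=cfg)
        mask = clean_mask(mask, k=1, config=cfg)
        report.record("segmentation", True)
    except ValueError as e:
        report.record("segmentation", False, str(e))
        report.missing_labels = toe_labels + deep_labels
        return ExtractionResult(empty, report)

    try:
        aligned_mask, rotation = align_foot_vertical(mask)
        report.record("alignment", True, f"rotation={rotation:.2f}")
    except ValueError as e:
        report.record("alignment", False, str(e))
        report.missing_labels = toe_labels + deep_labels
        return ExtractionResult(empty, report)

    center = ((t.pixels.shape[0] - 1) / 2.0, (t.pixels.shape[1] - 1) / 2.0)
    v_aligned = VisualImage(np.stack(
        [rotate_array(v_reg.pixels[..., ch].astype(float), rotation,
                      order=1).clip(0, 255).astype(np.uint8)
         for ch in range(3)], axis=-1))
    t_aligned = ThermalImage(
        rotate_array(t.pixels, rotation, order=1,
                     cval=float(np.min(t.pixels))),
        region="foot", side=t.side, source_path=t.source_path)

    rois: list[ROI] = []
    taken = np.zeros_like(mask.bits)

    def add(label: int, shape: shp.Shape, raster: np.ndarray) -> bool:
        m = raster & mask.bits & ~taken
        if not m.any():
            return False
        rois.append(ROI(label=label, shape=shape, mask=BinaryMask(m)))
        taken[m] = True
        return True

    # --- toes (aligned frame, then rotated back) ---
    toe_masks_aligned: list[np.ndarray] = []
    toe_named = []
    try:
        rows = np.flatnonzero(aligned_mask.bits.any(axis=1))
        top, bottom = rows[0], rows[-1]
        mid = (top + bottom) // 2
        edges = toe_edge_map(v_aligned, aligned_mask, fc["log_sigma"])
        edges = filter_spurious_edges(edges, v_aligned, fc["edge_min_len"],
                                      fc["edge_min_intensity"],
                                      fc["log_sigma"])
        contour = BinaryMask(_outer_contour(aligned_mask.bits))
        # closure runs on the upper-half crop so the main foot interior,
        # which touches the crop boundary, does not count as closed
        sl = slice(top, mid + 1)
        closed_crop = link_edge_endpoints(
            BinaryMask(edges.bits[sl]), BinaryMask(contour.bits[sl]))
        closed = np.zeros_like(aligned_mask.bits)
        closed[sl] = closed_crop.bits
        toe_named, toe_msgs = toe_regions(BinaryMask(closed),
                                          fc["toe_open_radius"], t.side)
        for msg in toe_msgs:
            report.warn(msg)
        report.record("toes", len(toe_named) == 5,
                      f"{len(toe_named)} toes found")
    except ValueError as e:
        report.record("toes", False, str(e))

    found_toe_names = set()
    for name, m_aligned in toe_named:
        toe_masks_aligned.append(m_aligned)
        m_back = rotate_array(m_aligned, -rotation, order=0) \
            if rotation != 0.0 else m_aligned
        lab = NAME_TO_LABEL[f"{name}_{side_tag}"]
        if add(lab, shp.Raster(m_back), m_back):
            found_toe_names.add(name)
        else:
            report.missing_labels.append(lab)
    for name in TOES:
        if name not in found_toe_names:
            lab = NAME_TO_LABEL[f"{name}_{side_tag}"]
            if lab not in report.missing_labels:
                report.missing_labels.append(lab)

    # --- ball of the foot and heel (aligned frame) ---
    wp = width_profile(aligned_mask)
    params = PlacementParams(
        beta=fc["beta"],
        tau=fc["tau_frac"] * float(wp.rows[-1] - wp.rows[0] + 1),
        alpha=fc["alpha"])

    toe_ref = None
    if toe_masks_aligned:
        rrows, rcols = [], []
        for m in toe_masks_aligned:
            pts = np.argwhere(m)
            rrows.append((pts[:, 0].min() + pts[:, 0].max()) / 2.0)
            rcols.append(pts[:, 1].mean())
        toe_ref = ToeRowRef(float(np.mean(rrows)), float(np.mean(rcols)))

    def add_deep(prefix: str, circ: shp.Circle) -> None:
        lab_c = NAME_TO_LABEL[f"{prefix}_circle_{side_tag}"]
        raster_c = shp.rasterise(circ, aligned_mask.bits.shape) \
            & aligned_mask.bits
        circ_back = _backmap_shape(circ, rotation, center)
        raster_back = rotate_array(raster_c, -rotation, order=0) \
            if rotation != 0.0 else raster_c
        if not add(lab_c, circ_back, raster_back):
            report.missing_labels.append(lab_c)
        qp = place_quads(circ, wp, params, toe_masks_aligned, aligned_mask,
                         fc["min_quad_area_frac"])
        # quad_1 is the medial (hallux-side) quadrilateral: image-left of
        # the circle on a right foot, image-right on a left foot
        if t.side == "right":
            pairs = (("quad_1", qp.q1), ("quad_2", qp.q2))
        else:
            pairs = (("quad_1", qp.q2), ("quad_2", qp.q1))
        for qname, quad in pairs:
            lab_q = NAME_TO_LABEL[f"{prefix}_{qname}_{side_tag}"]
            if quad is None:
                report.missing_labels.append(lab_q)
                report.warn(f"{prefix} {qname} shrunk away during "
                            "overlap resolution")
                continue
            raster_q = shp.rasterise(quad, aligned_mask.bits.shape) \
                & aligned_mask.bits & ~raster_c
            quad_back = _backmap_shape(quad, rotation, center)
            raster_qb = rotate_array(raster_q, -rotation, order=0) \
                if rotation != 0.0 else raster_q
            if not add(lab_q, quad_back, raster_qb):
                report.missing_labels.append(lab_q)

    if toe_ref is not None:
        try:
            circ = bof_circle(wp, toe_ref, params)
            add_deep("bof", circ)
            report.record("bof", True)
        except (ValueError, KeyError) as e:
            report.record("bof", False, str(e))
            report.missing_labels += [NAME_TO_LABEL[f"bof_{s}_{side_tag}"]
                                      for s in ("circle", "quad_1", "quad_2")]
    else:
        report.record("bof", False, "no toe reference available")
        report.missing_labels += [NAME_TO_LABEL[f"bof_{s}_{side_tag}"]
                                  for s in ("circle", "quad_1", "quad_2")]

    try:
        hcirc = heel_circle(t_aligned, aligned_mask, params,
                            fc["heel_hough_diam_frac"],
                            fc["sobel_percentile"])
        add_deep("heel", hcirc)
        report.record("heel", True)
    except (ValueError, KeyError) as e:
        report.record("heel", False, str(e))
        report.missing_labels += [NAME_TO_LABEL[f"heel_{s}_{side_tag}"]
                                  for s in ("circle", "quad_1", "quad_2")]

    rs = ROISet(rois, image_ref=t.source_path, region="foot")
    return ExtractionResult(rs, report, foreground=mask)
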