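"""Synthetic limb phantoms with exact ground-truth ROI masks.

Every phantom is a parametric-geometry render (no learned textures), so
its ground truth is exact by construction:

* hand — palm ellipse + forearm stub + five capsule fingers splayed per
  side, warm core (33 degC) fading toward the fingertips over a 22 degC
  background: the good foreground contrast of hand/shin thermograms.
* shin — two tapering near-vertical trapezoids with a warm medial ridge.
* foot — a single foot (toes up) whose skin runs only ~2 degC above
  background (the poor thermal contrast that forces the visual-image
  route), plus a paired pseudo-visual photograph on its own camera grid:
  bright foot on dark background, dark inter-toe grooves, per-toe crease
  lines, mild shading and weak illumination streaks, related to the
  thermal grid by a known affine with >= 3 emitted landmark pairs.  A
  warmer heel pad provides the thermal edges for the heel Hough circle.

Temperatures carry additive Gaussian sensor noise (default SD 0.02 degC,
a 20 mK NETD-class camera); the seed fixes all randomness bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from . import shapes as shp
from .foot_pipeline import (PlacementParams, ToeRowRef, bof_circle,
                            place_quads, width_profile)
from .geometry import apply_affine, invert_affine, rot_matrix, rotate_array
from .hand_pipeline import DEFAULT_PALM_TEMPLATE, solve_affine_3pt
from .labels import NAME_TO_LABEL, SHIN_PARTS, TOES
from .thermal_io import ROI, BinaryMask, ROISet, ThermalImage, VisualImage

__all__ = ["PhantomSpec", "PhantomOutput", "generate_hand_phantom",
           "generate_shin_phantom", "generate_foot_phantom",
           "generate_phantom"]


@dataclass
class PhantomSpec:
    """Study conditions of one synthetic acquisition."""

    region: str = "hand"
    side: str = "right"
    height: int = 256
    width: int = 320
    background_temp: float = 22.0
    core_temp: float = 33.0
    extremity_temp: float = 24.0
    noise_sd: float = 0.02
    pose_angle: float = 0.0
    seed: int = 0
    geometry: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.region in ("hand", "shin") and \
                self.core_temp <= self.background_temp:
            raise ValueError("core_temp must exceed background_temp")


@dataclass
class PhantomOutput:
    thermal: ThermalImage
    truth: ROISet
    visual: VisualImage | None = None
    landmarks: tuple[np.ndarray, np.ndarray] | None = None  # (vis, therm)
    meta: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# raster helpers

def _grid(h, w):
    return np.mgrid[0:h, 0:w].astype(float)


def _ellipse_mask(h, w, center, semi) -> np.ndarray:
    rr, cc = _grid(h, w)
    return ((rr - center[0]) / semi[0]) ** 2 + \
           ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _capsule_mask(h, w, p0, p1, radius) -> tuple[np.ndarray, np.ndarray]:
    """Mask of points within ``radius`` of segment p0-p1, plus the
    normalized arc-length coordinate (0 at p0) of each pixel."""
    rr, cc = _grid(h, w)
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L = np.hypot(*d)
    u = d / L
    vr, vc = rr - p0[0], cc - p0[1]
    t = np.clip(vr * u[0] + vc * u[1], 0.0, L)
    dist = np.hypot(vr - t * u[0], vc - t * u[1])
    return dist <= radius, t / L


def _mirror_shape(s: shp.Shape, w: int) -> shp.Shape:
    last = w - 1.0
    if isinstance(s, shp.Circle):
        return shp.Circle((s.center[0], last - s.center[1]), s.radius)
    if isinstance(s, shp.Quadrilateral):
        return shp.Quadrilateral(tuple((v[0], last - v[1])
                                       for v in s.vertices))
    if isinstance(s, shp.RotatedRect):
        return shp.RotatedRect((s.center[0], last - s.center[1]),
                               s.width, s.height, -s.angle)
    if isinstance(s, shp.Raster):
        return shp.Raster(s.mask[:, ::-1])
    raise TypeError(type(s))


def _assemble_truth(entries, region, fg, image_ref="phantom") -> ROISet:
    """Build a disjoint truth ROISet: each mask is the shape raster
    clipped to the foreground and to the complement of earlier entries."""
    rois, taken = [], np.zeros_like(fg)
    for label, shape in entries:
        raster = shp.rasterise(shape, fg.shape) if not isinstance(shape, shp.Raster) \
            else shape.mask
        m = raster & fg & ~taken
        if not m.any():
            raise ValueError(f"phantom truth ROI {label} is empty")
        taken |= m
        rois.append(ROI(label=label, shape=shape, mask=BinaryMask(m)))
    return ROISet(rois, image_ref=image_ref, region=region)


# ---------------------------------------------------------------------------
# hand

_FINGER_ANGLES = {"thumb": 155.0, "index": 115.0, "middle": 92.0,
                  "ring": 70.0, "little": 48.0}
_FINGER_LENGTHS = {"thumb": 50.0, "index": 68.0, "middle": 75.0,
                   "ring": 68.0, "little": 52.0}


def generate_hand_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Right-handed construction; the left side mirrors the whole render.

    Geometry knobs (``spec.geometry``): ``finger_halfwidth`` (default 7),
    ``palm_semi`` (48, 40), ``forearm_halfwidth`` (28).
    """
    if spec.region != "hand":
        raise ValueError("region must be 'hand'")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    g = spec.geometry
    fw = float(g.get("finger_halfwidth", 7.0))
    palm_semi = np.asarray(g.get("palm_semi", (48.0, 40.0)), float)
    fore_hw = float(g.get("forearm_halfwidth", 28.0))

    palm_c = np.array([155.0, 160.0]) + rng.uniform(-3, 3, 2)
    ang_jit = rng.uniform(-3, 3, 5)
    len_jit = rng.uniform(0.95, 1.05, 5)
    pose = rot_matrix(spec.pose_angle)

    def place(p):  # rotate about the palm center by the pose angle
        return palm_c + pose @ (np.asarray(p, float) - palm_c)

    silhouette = _ellipse_mask(h, w, palm_c, palm_semi)
    if spec.pose_angle:   # rotated palm ellipse via coordinate transform
        rr, cc = _grid(h, w)
        rel = np.stack([rr - palm_c[0], cc - palm_c[1]])
        inv = rot_matrix(-spec.pose_angle)
        rl = inv[0, 0] * rel[0] + inv[0, 1] * rel[1]
        cl = inv[1, 0] * rel[0] + inv[1, 1] * rel[1]
        silhouette = (rl / palm_semi[0]) ** 2 + (cl / palm_semi[1]) ** 2 <= 1

    temp = np.full((h, w), np.nan)
    rr, cc = _grid(h, w)

    # palm dome: core at the center, ~1.5 degC cooler at the rim
    rel = np.stack([rr - palm_c[0], cc - palm_c[1]])
    inv = rot_matrix(-spec.pose_angle)
    rl = inv[0, 0] * rel[0] + inv[0, 1] * rel[1]
    cl = inv[1, 0] * rel[0] + inv[1, 1] * rel[1]
    rho2 = (rl / palm_semi[0]) ** 2 + (cl / palm_semi[1]) ** 2
    temp[silhouette] = spec.core_temp - 1.5 * np.clip(rho2, 0, 1)[silhouette]

    # forearm stub from the palm bottom to the image edge
    fore_p0 = place(palm_c + np.array([palm_semi[0] * 0.8, 0.0]))
    fore_dir = pose @ np.array([1.0, 0.0])
    fore_p1 = fore_p0 + fore_dir * (h - fore_p0[0]) / max(fore_dir[0], 0.3)
    fore_mask, fore_s = _capsule_mask(h, w, fore_p0, fore_p1, fore_hw)
    add = fore_mask & ~silhouette
    ur = (rr - fore_p0[0]) * fore_dir[1] - (cc - fore_p0[1]) * fore_dir[0]
    temp[add] = spec.core_temp - 0.8 - 1.2 * (ur[add] / fore_hw) ** 2
    silhouette |= fore_mask

    fingers: dict[str, dict] = {}
    for i, name in enumerate(_FINGER_ANGLES):
        th = np.deg2rad(_FINGER_ANGLES[name] + ang_jit[i])
        d = np.array([-np.sin(th), np.cos(th)])
        # ellipse radius along d, then base just inside the rim
        r_ell = 1.0 / np.sqrt((d[0] / palm_semi[0]) ** 2 +
                              (d[1] / palm_semi[1]) ** 2)
        base = place(palm_c + 0.97 * r_ell * d)
        length = _FINGER_LENGTHS[name] * len_jit[i]
        d_img = pose @ d
        tip_end = base + length * d_img
        cap, s = _capsule_mask(h, w, base, tip_end, fw)
        add = cap & ~silhouette
        temp[add] = spec.core_temp - 1.0 - 2.0 * s[add]
        silhouette |= cap
        # the capsule's rounded end cap is centered on the segment end,
        # so the ground-truth fingertip disc sits exactly there
        fingers[name] = {"base": base, "dir": d_img, "length": length,
                         "tip_center": tip_end, "capsule": cap}

    noise = rng.normal(0.0, spec.noise_sd, (h, w))
    pixels = np.where(silhouette, temp, spec.background_temp) + noise

    side_tag = "R" if spec.side == "right" else "L"
    # truth palm placement follows the anchor rule applied to the ideal
    # silhouette: split fingers off by opening the noise-free mask at the
    # finger scale, then take each finger's major-axis base point (the
    # same definition the extraction uses, evaluated on exact geometry)
    from .hand_pipeline import _axis_boundary_hits, _blob_axis
    from .morpho import binary_opening_disc
    from scipy import ndimage as _ndi
    palm_true = binary_opening_disc(silhouette, int(round(fw)) + 2)
    resid = silhouette & ~palm_true
    palm_centroid = np.argwhere(palm_true).mean(axis=0)
    anchors = []
    for name in ("thumb", "index", "little"):
        # restrict the residual to the finger's own (exactly known)
        # capsule so adjacent-finger slivers cannot merge components
        comp = resid & fingers[name]["capsule"]
        lab_c, nlab = _ndi.label(comp, structure=np.ones((3, 3), bool))
        if nlab > 1:
            areas = np.bincount(lab_c.ravel())[1:]
            comp = lab_c == (int(np.argmax(areas)) + 1)
        ctr, axis = _blob_axis(comp)
        from .hand_pipeline import FingerBlob
        hits = _axis_boundary_hits(FingerBlob(comp, ctr, axis))
        dists = [np.hypot(*(hh - palm_centroid)) for hh in hits]
        anchors.append(hits[int(np.argmin(dists))])
    anchors = np.asarray(anchors)
    mat = solve_affine_3pt(DEFAULT_PALM_TEMPLATE.anchor_points, anchors)
    palm_shapes = [shp.transform_shape(s, mat)
                   for s in DEFAULT_PALM_TEMPLATE.roi_shapes]
    tip_shapes = [shp.Circle(tuple(fingers[f]["tip_center"]), fw)
                  for f in _FINGER_ANGLES]

    if spec.side == "left":
        pixels = pixels[:, ::-1]
        silhouette = silhouette[:, ::-1]
        tip_shapes = [_mirror_shape(s, w) for s in tip_shapes]
        palm_shapes = [_mirror_shape(s, w) for s in palm_shapes]
        for f in fingers.values():
            f["tip_center"][1] = w - 1 - f["tip_center"][1]
            f["base"][1] = w - 1 - f["base"][1]

    entries = [(NAME_TO_LABEL[f"finger_{f}_{side_tag}"], s)
               for f, s in zip(_FINGER_ANGLES, tip_shapes)]
    entries += [(NAME_TO_LABEL[f"{p}_{side_tag}"], s)
                for p, s in zip(("palm_thenar", "palm_center",
                                 "palm_hypothenar"), palm_shapes)]
    truth = _assemble_truth(entries, "hand", silhouette)
    thermal = ThermalImage(pixels, region="hand", side=spec.side,
                           source_path=f"phantom:hand:{spec.seed}")
    return PhantomOutput(thermal, truth,
                         meta={"finger_halfwidth": fw,
                               "fingers": fingers,
                               "silhouette": silhouette})


# ---------------------------------------------------------------------------
# shin

def generate_shin_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Two tapering near-vertical shins; ROI truth follows the placement
    rule applied to the analytic trapezoid geometry.

    Geometry knobs: ``top_width`` (56), ``taper`` (12), ``length`` (205).
    """
    if spec.region != "shin":
        raise ValueError("region must be 'shin'")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    g = spec.geometry
    top_w = float(g.get("top_width", 56.0))
    taper = float(g.get("taper", 12.0))
    length = float(g.get("length", 205.0))

    pixels = np.full((h, w), spec.background_temp)
    silhouette = np.zeros((h, w), dtype=bool)
    rr, cc = _grid(h, w)
    truth_entries = []
    pose = spec.pose_angle

    for side_tag, c0 in (("R", 110.0), ("L", 210.0)):
        cx = c0 + rng.uniform(-4, 4)
        top_row = 25.0 + rng.uniform(-3, 3)
        L = length + rng.uniform(-5, 5)
        wt = top_w + rng.uniform(-3, 3)
        wb = wt - taper + rng.uniform(-2, 2)
        center = np.array([top_row + L / 2.0, cx])
        R = rot_matrix(pose)
        axis = R @ np.array([1.0, 0.0])      # down-limb direction
        across = R @ np.array([0.0, 1.0])
        p_top = center - axis * L / 2.0
        quad = shp.Quadrilateral((
            tuple(p_top - across * wt / 2.0),
            tuple(p_top + across * wt / 2.0),
            tuple(p_top + axis * L + across * wb / 2.0),
            tuple(p_top + axis * L - across * wb / 2.0)))
        m = shp.rasterise(quad, (h, w))
        # warm medial ridge, cooling toward the edges and slightly downward
        s_axis = (rr - p_top[0]) * axis[0] + (cc - p_top[1]) * axis[1]
        u = (rr - p_top[0]) * across[0] + (cc - p_top[1]) * across[1]
        frac = np.clip(s_axis / L, 0, 1)
        local_hw = (wt + (wb - wt) * frac) / 2.0
        tt = spec.core_temp - 1.0 * frac - \
            1.2 * (u / np.maximum(local_hw, 1.0)) ** 2
        pixels[m] = tt[m]
        silhouette |= m

        # truth: reference points at arc fractions of the medial line,
        # widths emulating the per-row horizontal-span convention
        cospose = np.cos(np.deg2rad(pose))
        medial_angle = np.degrees(np.arctan2(1.0, axis[1] / axis[0])) \
            if axis[0] != 0 else 90.0
        height_roi = 0.12 * L
        for part, fracpt in zip(SHIN_PARTS, (0.06, 0.5, 0.75)):
            pcen = p_top + axis * (fracpt * L)
            wloc = (wt + (wb - wt) * fracpt) / cospose
            rect = shp.RotatedRect(tuple(pcen), 0.6 * wloc, height_roi, pose)
            truth_entries.append((NAME_TO_LABEL[f"{part}_{side_tag}"], rect))

    pixels = pixels + rng.normal(0.0, spec.noise_sd, (h, w))
    truth = _assemble_truth(truth_entries, "shin", silhouette)
    thermal = ThermalImage(pixels, region="shin", side="both",
                           source_path=f"phantom:shin:{spec.seed}")
    return PhantomOutput(thermal, truth, meta={"silhouette": silhouette})


# ---------------------------------------------------------------------------
# foot

_TOE_COLS = (121.0, 140.5, 158.0, 174.5, 190.0)
_TOE_SEMI_R = (22.0, 20.0, 19.0, 18.0, 17.0)
_TOE_SEMI_C = (12.0, 10.0, 9.5, 9.0, 8.5)


def _draw_line_band(canvas: np.ndarray, p0, p1, value: float,
                    halfwidth: float) -> np.ndarray:
    """Paint a straight band of the given half-width onto ``canvas``;
    returns the painted mask."""
    m, _ = _capsule_mask(canvas.shape[0], canvas.shape[1], p0, p1, halfwidth)
    canvas[m] = value
    return m


def generate_foot_phantom(spec: PhantomSpec) -> PhantomOutput:
    """One foot, toes at the top, plus a paired pseudo-visual image.

    The thermal foot sits ``extremity_temp`` (default 24 degC) over a
    22 degC background — deliberately poor contrast — with a warmer heel
    pad disc; the visual image carries the segmentation and toe
    information.  The visual camera grid (default 320x400) maps to the
    thermal grid through a known similarity (scale 0.64, rotation 2 deg)
    emitted as 4 landmark pairs.
    """
    if spec.region != "foot":
        raise ValueError("region must be 'foot'")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    g = spec.geometry
    cx = 160.0 + rng.uniform(-5, 5)
    dcx = cx - 160.0
    blade_top, blade_bot, cap_bot = 64.0, 220.0, 232.0
    hw_top = float(g.get("blade_halfwidth_top", 42.0)) + rng.uniform(-1, 1)
    hw_bot = float(g.get("blade_halfwidth_bottom", 47.0)) + rng.uniform(-1, 1)
    pad_center = np.array([194.0 + rng.uniform(-2, 2), cx + rng.uniform(-2, 2)])
    pad_radius = 26.0

    rr, cc = _grid(h, w)

    def top_edge(col):
        return blade_top + 0.0 * np.asarray(col, float)

    # the sole widens from the metatarsals toward the heel, so the upper
    # (toe) half of the width profile is the narrower one
    hw_r = hw_top + (hw_bot - hw_top) * np.clip(
        (rr - 130.0) / (blade_bot - 130.0), 0, 1)
    blade = (rr >= blade_top) & (rr <= blade_bot) & (np.abs(cc - cx) <= hw_r)
    cap = (rr > blade_bot) & (rr <= cap_bot) & \
        (np.abs(cc - cx) <= hw_bot * np.sqrt(np.maximum(
            1 - ((rr - blade_bot) / (cap_bot - blade_bot)) ** 2, 0)))

    toe_scale = rng.uniform(0.97, 1.03, 5)
    toe_masks_full = []
    toes_union = np.zeros((h, w), dtype=bool)
    toe_params = []
    for i in range(5):
        col = _TOE_COLS[i] + dcx + rng.uniform(-1, 1)
        semi = (_TOE_SEMI_R[i] * toe_scale[i], _TOE_SEMI_C[i] * toe_scale[i])
        # the toe base overlaps the (arched) blade top edge by ~6 px
        row = float(top_edge(col)) - semi[0] + 6.0 + rng.uniform(-1, 1)
        m = _ellipse_mask(h, w, (row, col), semi)
        toe_masks_full.append(m)
        toes_union |= m
        toe_params.append(((row, col), semi))

    silhouette = blade | cap | toes_union

    # geometry of the four inter-toe grooves
    groove_specs = []
    groove_cols = []
    for i in range(4):
        (r0, c0), s0 = toe_params[i]
        (r1, c1), s1 = toe_params[i + 1]
        gc_ = (c0 + s0[1] + c1 - s1[1]) / 2.0
        groove_cols.append(gc_)
        top_row = max(r0 - s0[0], r1 - s1[0]) + 6.0
        groove_specs.append((gc_, top_row))

    # ---- visual content on the thermal grid ----
    vis = np.full((h, w), 40.0)
    shade = 0.04 * (cc - cx) - 0.03 * (rr - 130.0)
    vis[silhouette] = 200.0 + shade[silhouette]
    # inter-toe groove shadows: sharp against one toe, fading toward the
    # other, so the edge detector sees a single separating chain; they
    # run down into the metatarsal crease, forming a connected web of
    # skin folds
    for gc_, top_row in groove_specs:
        bottom = float(top_edge(gc_)) + 4.0
        for dc in range(13):
            val = 120.0 + 80.0 * dc / 12.0
            band = _capsule_mask(h, w, (top_row, gc_ - 1.0 + dc),
                                 (bottom, gc_ - 1.0 + dc), 0.8)[0]
            band &= silhouette & (vis > val)
            vis[band] = val
    crease_rows = []
    for i in range(5):
        (r0, c0), s0 = toe_params[i]
        crow = float(top_edge(c0)) + 2.5
        crease_rows.append(crow)
        # the outermost creases dip diagonally to the foot margin, as the
        # skin folds under the first and fifth toe do
        if i == 0:
            p0 = (crow + 14.0, c0 - s0[1] - 9.0)
            p1 = (crow, c0 + s0[1] - 0.5)
        elif i == 4:
            p0 = (crow, c0 - s0[1] + 0.5)
            p1 = (crow + 14.0, c0 + s0[1] + 9.0)
        else:
            p0 = (crow, c0 - s0[1] + 0.5)
            p1 = (crow, c0 + s0[1] - 0.5)
        # crease shadows have a sharp upper edge and fade downward, so
        # the edge detector sees a single chain, not a parallel pair
        for dr in range(17):
            val = 120.0 + 80.0 * dr / 16.0
            band = _capsule_mask(h, w, (p0[0] + dr, p0[1]),
                                 (p1[0] + dr, p1[1]), 0.8)[0]
            band &= silhouette & (vis > val)
            vis[band] = val
    # weak illumination streaks exercising the spurious-edge filter
    for _ in range(2):
        sr = rng.uniform(85, 105)
        sc = cx + rng.uniform(-20, 20)
        ang = rng.uniform(0, np.pi)
        d = np.array([np.sin(ang), np.cos(ang)]) * 9.0
        _draw_line_band(vis, (sr - d[0], sc - d[1]), (sr + d[0], sc + d[1]),
                        190.0, 0.7)
    vis = np.clip(vis, 0, 255)

    # ---- thermal ----
    temp = np.full((h, w), spec.background_temp)
    toe_cool = 0.5 * np.clip((90.0 - rr) / 60.0, 0, 1)
    temp[silhouette] = spec.extremity_temp - toe_cool[silhouette]
    pad = _ellipse_mask(h, w, pad_center, (pad_radius, pad_radius))
    pad &= silhouette
    temp[pad] = spec.extremity_temp + 1.5
    temp = temp + rng.normal(0.0, spec.noise_sd, (h, w))

    # ---- truth ROIs ----
    side_tag = "R" if spec.side == "right" else "L"
    truth_toe_masks = []
    taken = np.zeros((h, w), dtype=bool)
    for i in range(5):
        m = toe_masks_full[i] & silhouette & (rr <= crease_rows[i] - 1) \
            & ~taken
        truth_toe_masks.append(m)
        taken |= m

    wp = width_profile(BinaryMask(silhouette))
    rows_fg = np.flatnonzero(silhouette.any(axis=1))
    foot_len = float(rows_fg[-1] - rows_fg[0] + 1)
    params = PlacementParams(beta=0.3, tau=0.35 * foot_len, alpha=0.25)
    bbox_rows = [(np.argwhere(m)[:, 0].min() + np.argwhere(m)[:, 0].max()) / 2
                 for m in truth_toe_masks]
    ref = ToeRowRef(float(np.mean(bbox_rows)),
                    float(np.mean([np.argwhere(m)[:, 1].mean()
                                   for m in truth_toe_masks])))
    circ = bof_circle(wp, ref, params)
    qp = place_quads(circ, wp, params, truth_toe_masks,
                     BinaryMask(silhouette))
    wh, ch = wp.at(int(round(pad_center[0])))
    heel_circ = shp.Circle((float(pad_center[0]), ch), params.beta * wh / 2.0)
    hq = place_quads(heel_circ, wp, params, truth_toe_masks,
                     BinaryMask(silhouette))

    # toe identity survives mirroring (the hallux stays toe_1; only its
    # image position flips), so the mapping is positional-index agnostic
    entries = []
    for i in range(5):
        entries.append((NAME_TO_LABEL[f"{TOES[i]}_{side_tag}"],
                        shp.Raster(truth_toe_masks[i])))
    circ_raster = shp.rasterise(circ, (h, w)) & silhouette
    entries.append((NAME_TO_LABEL[f"bof_circle_{side_tag}"], circ))
    for nm, q in (("bof_quad_1", qp.q1), ("bof_quad_2", qp.q2)):
        if q is not None:
            entries.append((NAME_TO_LABEL[f"{nm}_{side_tag}"], q))
    entries.append((NAME_TO_LABEL[f"heel_circle_{side_tag}"], heel_circ))
    for nm, q in (("heel_quad_1", hq.q1), ("heel_quad_2", hq.q2)):
        if q is not None:
            entries.append((NAME_TO_LABEL[f"{nm}_{side_tag}"], q))

    # ---- optional pose rotation, then mirroring for the left side ----
    if spec.pose_angle:
        temp = rotate_array(temp, spec.pose_angle, order=1,
                            cval=spec.background_temp)
        vis = rotate_array(vis, spec.pose_angle, order=1, cval=40.0)
        silhouette = rotate_array(silhouette, spec.pose_angle, order=0)
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
        from .geometry import rotation_about
        rmat = rotation_about(spec.pose_angle, center)
        entries = [(lab, shp.Raster(rotate_array(s.mask, spec.pose_angle,
                                                 order=0))
                    if isinstance(s, shp.Raster)
                    else shp.transform_shape(s, rmat))
                   for lab, s in entries]
        pad_center = apply_affine(rmat, pad_center)

    if spec.side == "left":
        temp = temp[:, ::-1]
        vis = vis[:, ::-1]
        silhouette = silhouette[:, ::-1]
        entries = [(lab, _mirror_shape(s, w)) for lab, s in entries]
        pad_center = np.array([pad_center[0], w - 1 - pad_center[1]])

    truth = _assemble_truth(entries, "foot", silhouette)

    # ---- render the visual camera grid and the landmark pairs ----
    vh, vw = int(g.get("visual_height", 320)), int(g.get("visual_width", 400))
    scale, rot_deg = 0.64, 2.0
    lin = rot_matrix(rot_deg) * scale
    c_v = np.array([(vh - 1) / 2.0, (vw - 1) / 2.0])
    c_t = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    off = c_t - lin @ c_v
    T = np.hstack([lin, off[:, None]])       # visual -> thermal
    visual_pixels = ndimage.affine_transform(
        vis, T[:, :2], offset=T[:, 2], output_shape=(vh, vw), order=1,
        mode="constant", cval=40.0)
    visual = VisualImage(np.clip(np.rint(visual_pixels), 0, 255
                                 ).astype(np.uint8)[..., None].repeat(3, -1))
    therm_pts = np.array([[40.0, 60.0], [40.0, 260.0],
                          [220.0, 60.0], [220.0, 260.0]])
    inv = invert_affine(T)
    vis_pts = apply_affine(inv, therm_pts)

    thermal = ThermalImage(temp, region="foot", side=spec.side,
                           source_path=f"phantom:foot:{spec.seed}")
    return PhantomOutput(thermal, truth, visual=visual,
                         landmarks=(vis_pts, therm_pts),
                         meta={"affine": T, "pad_center": pad_center,
                               "silhouette": silhouette,
                               "groove_cols": groove_cols})


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    gen = {"hand": generate_hand_phantom, "shin": generate_shin_phantom,
           "foot": generate_foot_phantom}[spec.region]
    return gen(spec)
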