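"""Extraction of the 8 hand regions: 5 fingertip discs + 3 palm regions.

The cascade: adaptive thresholding segments the hand; iterative
morphological opening with growing disc structuring elements yields the
area profile A(r), whose first sharp drop (located by a moving-window
variance detector) gives the finger scale; opening at that scale splits
fingers from palm+forearm; finger blobs are named by the angles they
subtend at the palm centroid (the widest pair being thumb and little
finger); the thumb/index/little base points anchor an affine fit of the
palm template; and a circle Hough transform on each finger's edge map
places the fingertip disc.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import hough_circle, hough_circle_peaks

from . import shapes as shp
from .config import resolve
from .geometry import rot_matrix
from .labels import FINGERS, NAME_TO_LABEL
from .morpho import binary_opening_disc
from .reporting import ExtractionResult, PipelineReport
from .segmentation import adaptive_threshold, clean_mask
from .thermal_io import ROI, BinaryMask, ROISet, ThermalImage

__all__ = [
    "OpeningProfile", "VarianceDetectorParams", "PalmTemplate",
    "LabelledFingers", "FingerBlob",
    "opening_profile", "finger_radius", "split_fingers", "label_fingers",
    "palm_anchor_points", "fit_palm_template", "fingertip_circles",
    "extract_hand_rois", "DEFAULT_PALM_TEMPLATE",
]


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class OpeningProfile:
    """Foreground area A(r) after opening with disc SEs of radius r."""

    radii: np.ndarray
    areas: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=int))
        object.__setattr__(self, "areas", np.asarray(self.areas, dtype=float))
        if np.any(np.diff(self.areas) > 0):
            raise ValueError("A(r) must be non-increasing in r")


@dataclass(frozen=True)
class VarianceDetectorParams:
    """Moving-window variance detector settings.

    ``window_N``: size N of the moving window around r.
    ``ref_factor``: detection fires when the window variance exceeds the
    reference (mean variance of the first three windows visited) by this
    factor.
    """

    window_N: int = 5
    ref_factor: float = 20.0

    def __post_init__(self):
        if self.window_N < 2:
            raise ValueError("window_N must be >= 2")
        if self.ref_factor <= 1:
            raise ValueError("ref_factor must exceed 1")


@dataclass(frozen=True)
class PalmTemplate:
    """Three anchor points and three palm ROI shapes in template coords.

    Anchors are the base points of the thumb, index and little fingers, in
    that order.
    """

    anchor_points: np.ndarray            # (3, 2) rows of (row, col)
    roi_shapes: tuple[shp.Shape, ...]    # palm_thenar, palm_center, palm_hypothenar

    def __post_init__(self):
        pts = np.asarray(self.anchor_points, dtype=float)
        object.__setattr__(self, "anchor_points", pts)
        if pts.shape != (3, 2):
            raise ValueError("need exactly 3 anchor points")
        if abs(_signed_area(pts)) < 1e-9:
            raise ValueError("template anchors are collinear")
        if len(self.roi_shapes) != 3:
            raise ValueError("need exactly 3 palm ROI shapes")


@dataclass
class FingerBlob:
    mask: np.ndarray
    centroid: np.ndarray
    axis: np.ndarray  # unit major-axis direction (row, col)


@dataclass
class LabelledFingers:
    """Finger-name -> blob map; exactly the five anatomical fingers."""

    fingers: dict[str, FingerBlob] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.fingers) != set(FINGERS):
            raise ValueError(f"need exactly the fingers {FINGERS}")


def _signed_area(pts: np.ndarray) -> float:
    a, b, c = pts
    return 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))


# The palm template layout: anchors at the thumb / index / little finger
# bases, three quadrilateral palm regions (thenar, central, hypothenar)
# between them.  Coordinates are an arbitrary template frame; the affine
# fit carries them onto each image.  User-replaceable via JSON.
def _square(center, side):
    r, c = center
    h = side / 2.0
    return shp.Quadrilateral(((r - h, c - h), (r - h, c + h),
                              (r + h, c + h), (r + h, c - h)))


DEFAULT_PALM_TEMPLATE = PalmTemplate(
    anchor_points=np.array([[138.1, 123.8],   # thumb base
                            [114.4, 141.1],   # index base
                            [123.4, 188.5]]),  # little base
    roi_shapes=(_square((158.0, 136.0), 22.0),
                _square((146.0, 161.0), 24.0),
                _square((153.0, 184.0), 20.0)),
)


# ---------------------------------------------------------------------------
# operations

def opening_profile(m: BinaryMask, r_max: int | None = None) -> OpeningProfile:
    """A(r) for r = 1..r_max by opening with disc SEs of radius r.

    Default r_max is half the shorter side of the mask's bounding box.

    Openings with rasterised discs can transiently regain a pixel or two
    as the disc shape changes between consecutive integer radii; the
    profile records the running-minimum envelope of the exact opening
    areas so that A(r) is non-increasing, as the drop detector assumes
    (asserted by the profile type).
    """
    bits = m.bits
    if not bits.any():
        raise ValueError("empty mask")
    if r_max is None:
        rows = np.any(bits, axis=1).nonzero()[0]
        cols = np.any(bits, axis=0).nonzero()[0]
        minor = min(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
        r_max = max(int(minor // 2), 1)
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    radii = np.arange(1, r_max + 1)
    areas = np.empty(radii.size, dtype=float)
    for i, r in enumerate(radii):
        areas[i] = int(binary_opening_disc(bits, int(r)).sum())
    return OpeningProfile(radii, np.minimum.accumulate(areas))


def variance_signal(p, window_N: int) -> tuple[np.ndarray, np.ndarray]:
    """V(r) = sum over the window [r-N/2, r+N/2] of (A - mean)^2 / (N - 1).

    Returns (valid indices into p.radii, V values at those indices).
    """
    half = window_N // 2
    a = p.areas if isinstance(p, OpeningProfile) else np.asarray(p, float)
    idx = np.arange(half, a.size - half)
    v = np.empty(idx.size)
    for j, i in enumerate(idx):
        w = a[i - half: i + half + 1]
        v[j] = np.sum((w - w.mean()) ** 2) / (window_N - 1)
    return idx, v


def finger_radius(p, params: VarianceDetectorParams | None = None) -> int:
    """Radius of the first sharp drop of A(r), via the variance detector.

    A moving-window variance V(r) is evaluated over the profile; starting
    from the midpoint of the non-zero support of A(r) and walking toward
    r = 0, the mean V of the first three windows establishes a reference,
    and the first r whose V exceeds reference x ref_factor is returned.
    The trailing all-zero tail of the profile (radii beyond extinction)
    is ignored when locating the midpoint, since it carries no shape
    information.

    ``p`` may be an OpeningProfile or a plain area sequence (implicit
    radii 1..n): the detector itself needs no monotonicity.
    """
    if params is None:
        params = VarianceDetectorParams()
    n = params.window_N
    if isinstance(p, OpeningProfile):
        areas, radii = p.areas, p.radii
    else:
        areas = np.asarray(p, dtype=float)
        radii = np.arange(1, areas.size + 1)
    if areas.size < 2 * n:
        raise ValueError("profile too short for the detector window")
    half = n // 2
    idx, v = variance_signal(areas, n)
    nz = np.nonzero(areas > 0)[0]
    support_end = nz[-1] + 1 if nz.size else areas.size
    mid = support_end // 2
    mid = int(np.clip(mid, idx[0] + 3, idx[-1]))  # need 3 reference windows
    vmap = dict(zip(idx.tolist(), v.tolist()))
    ref = np.mean([vmap[mid], vmap[mid - 1], vmap[mid - 2]])
    for i in range(mid - 3, idx[0] - 1, -1):
        if vmap[i] > ref * params.ref_factor and vmap[i] > 0:
            return int(radii[i])
    raise ValueError("no finger drop detected (flat profile)")


def split_fingers(m: BinaryMask, r: int, min_finger_area: int = 30
                  ) -> tuple[BinaryMask, BinaryMask]:
    """Split the hand mask into fingers and palm+forearm at disc radius r.

    palm_arm = opening(m, disc(r)); the five largest components of
    m minus palm_arm (above ``min_finger_area``) are the fingers.
    """
    bits = m.bits
    palm_arm = binary_opening_disc(bits, int(r))
    resid = bits & ~palm_arm
    lab, nlab = ndimage.label(resid, structure=np.ones((3, 3), bool))
    if nlab < 5:
        raise ValueError(f"only {nlab} finger candidates found (need 5)")
    areas = np.bincount(lab.ravel())[1:]
    order = np.argsort(areas, kind="stable")[::-1][:5]
    if areas[order[-1]] < min_finger_area:
        raise ValueError("fewer than 5 finger components above minimum area")
    fingers = np.isin(lab, [i + 1 for i in order])
    return BinaryMask(fingers), BinaryMask(palm_arm)


def _blob_axis(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit major-axis direction from second moments.

    Isotropic blobs (eigenvalues equal within 1e-9) take the vertical
    (row) direction as the tie-break.
    """
    pts = np.argwhere(mask).astype(float)
    ctr = pts.mean(axis=0)
    cov = np.cov((pts - ctr).T) if pts.shape[0] > 1 else np.eye(2)
    w, vecs = np.linalg.eigh(cov)
    if abs(w[1] - w[0]) <= 1e-9 * max(abs(w[1]), 1.0):
        axis = np.array([1.0, 0.0])
    else:
        axis = vecs[:, np.argmax(w)]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return ctr, axis


def label_fingers(fingers: BinaryMask, palm_centroid, side: str
                  ) -> LabelledFingers:
    """Name the five finger blobs from their angles at the palm centroid.

    Angles are measured in standard orientation (y up, i.e. -row).  The
    pair of fingers bounding the largest circular gap in the sorted
    angles subtends the largest angle: they are the thumb and the little
    finger.  For a right (volar) hand the thumb sits at the anticlockwise
    end of the finger span; for a left hand at the clockwise end.  The
    remaining fingers follow in angular order from the thumb.  The rule
    depends only on angular order, hence is rotation independent.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    lab, nlab = ndimage.label(fingers.bits, structure=np.ones((3, 3), bool))
    if nlab != 5:
        raise ValueError(f"expected exactly 5 finger components, got {nlab}")
    ctr0 = np.asarray(palm_centroid, dtype=float)
    blobs, angles = [], []
    for i in range(1, 6):
        mask = lab == i
        c, axis = _blob_axis(mask)
        blobs.append(FingerBlob(mask, c, axis))
        angles.append(np.arctan2(-(c[0] - ctr0[0]), c[1] - ctr0[1]))
    angles = np.asarray(angles)
    order = np.argsort(angles, kind="stable")
    sorted_ang = angles[order]
    gaps = np.diff(np.concatenate([sorted_ang, [sorted_ang[0] + 2 * np.pi]]))
    if np.min(gaps) < np.deg2rad(0.5):
        raise ValueError("degenerate geometry: two finger centroids are "
                         "collinear with the palm centroid")
    g = int(np.argmax(gaps))
    # span runs anticlockwise from the blob after the gap to the blob before it
    ccw = [order[(g + 1 + k) % 5] for k in range(5)]
    if side == "right":
        seq = ccw[::-1]   # thumb at the anticlockwise end
    else:
        seq = ccw         # mirrored hand: thumb at the clockwise end
    return LabelledFingers({name: blobs[j] for name, j in zip(FINGERS, seq)})


def _axis_boundary_hits(blob: FingerBlob, step: float = 0.25) -> list[np.ndarray]:
    """March along the major axis from the centroid to the blob boundary."""
    hits = []
    h, w = blob.mask.shape
    for sign in (1.0, -1.0):
        p = blob.centroid.copy()
        last_inside = p.copy()
        t = 0.0
        while True:
            t += step
            q = blob.centroid + sign * t * blob.axis
            i, j = int(round(q[0])), int(round(q[1]))
            if not (0 <= i < h and 0 <= j < w) or not blob.mask[i, j]:
                hits.append(last_inside)
                break
            last_inside = q
            if t > h + w:  # numerical guard; unreachable for connected blobs
                raise RuntimeError("axis never left the blob")
    return hits


def palm_anchor_points(lf: LabelledFingers, palm_centroid) -> np.ndarray:
    """Base points of thumb, index and little fingers, (3, 2) array.

    Each finger's major axis is intersected with its blob boundary; of
    the two intersection points the one nearest the palm centroid (the
    finger base) is kept.
    """
    ctr = np.asarray(palm_centroid, dtype=float)
    out = []
    for name in ("thumb", "index", "little"):
        blob = lf.fingers[name]
        hits = _axis_boundary_hits(blob)
        d = [np.hypot(*(h - ctr)) for h in hits]
        out.append(hits[int(np.argmin(d))])
    return np.asarray(out)


def solve_affine_3pt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """The unique 2x3 affine sending three source points to three targets."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if abs(_signed_area(src)) < 1e-9 or abs(_signed_area(dst)) < 1e-9:
        raise ValueError("collinear point triple: affine underdetermined")
    A = np.hstack([src, np.ones((3, 1))])
    sol = np.linalg.solve(A, dst)      # (3, 2): rows of [a, b; c, d; tr, tc]
    return sol.T                        # 2x3 acting on (row, col, 1)


def fit_palm_template(tmpl: PalmTemplate, anchors: np.ndarray,
                      hand_mask: BinaryMask | None = None) -> list[ROI | None]:
    """Map the template's palm shapes onto the image via a 3-point affine.

    Returns the three palm shapes transformed into image coordinates;
    rasterisation/clipping to the hand mask happens here when a mask is
    given.  Returned as a list of (shape, mask) ROI building blocks —
    labels are attached by the caller.
    """
    mat = solve_affine_3pt(tmpl.anchor_points, np.asarray(anchors, float))
    shapes = [shp.transform_shape(s, mat) for s in tmpl.roi_shapes]
    if hand_mask is None:
        return shapes
    out = []
    hw = hand_mask.bits.shape
    for s in shapes:
        m = shp.rasterise(s, hw) & hand_mask.bits
        out.append((s, m))
    return out


def _farthest_boundary_point(mask: np.ndarray, ref: np.ndarray) -> np.ndarray:
    er = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool),
                                border_value=0)
    boundary = np.argwhere(mask & ~er).astype(float)
    d = np.hypot(boundary[:, 0] - ref[0], boundary[:, 1] - ref[1])
    return boundary[int(np.argmax(d))]


def fingertip_circles(lf: LabelledFingers, palm_centroid,
                      radius_frac: tuple[float, float] = (0.25, 0.6),
                      ) -> dict[str, shp.Circle | None]:
    """Fingertip circle per finger via the circle Hough transform.

    Radii scan [radius_frac] x the blob's minor-axis width; among peak
    candidates the circle whose center is closest to the fingertip (the
    blob boundary point farthest from the palm centroid) wins; vote ties
    prefer the larger radius.  A finger with no circle maps to None.
    """
    ctr = np.asarray(palm_centroid, dtype=float)
    out: dict[str, shp.Circle | None] = {}
    for name, blob in lf.fingers.items():
        pts = np.argwhere(blob.mask).astype(float)
        rel = pts - blob.centroid
        cov = np.cov(rel.T)
        w, _ = np.linalg.eigh(cov)
        minor_width = 4.0 * np.sqrt(max(w[0], 0.25))  # ~full width of the blob
        r_lo = max(2, int(np.floor(radius_frac[0] * minor_width)))
        r_hi = max(r_lo + 1, int(np.ceil(radius_frac[1] * minor_width)))
        er = ndimage.binary_erosion(blob.mask, np.ones((3, 3), bool),
                                    border_value=0)
        edges = blob.mask & ~er
        radii = np.arange(r_lo, r_hi + 1)
        # raw vote counts: per-perimeter normalisation lets tiny circles
        # nestled into the base-cut corner outscore the fingertip cap
        acc = hough_circle(edges, radii, normalize=False).astype(float)
        votes, cols, rows, rads = hough_circle_peaks(
            acc, radii, total_num_peaks=20)
        if len(rads) == 0:
            out[name] = None
            continue
        tip = _farthest_boundary_point(blob.mask, ctr)
        # a fingertip circle lies on the finger: discard candidates whose
        # disc pokes substantially outside the blob (half-out circles
        # hugging the apex can collect spuriously many boundary votes)
        contained = []
        for v, c0, r0, rad in zip(votes, cols, rows, rads):
            disc = shp.rasterise(shp.Circle((float(r0), float(c0)),
                                            float(rad)), blob.mask.shape)
            n_disc = disc.sum()
            if n_disc == 0 or (disc & blob.mask).sum() / n_disc < 0.9:
                continue
            contained.append((float(v), float(r0), float(c0), float(rad)))
        if not contained:
            contained = [(float(v), float(r0), float(c0), float(rad))
                         for v, c0, r0, rad in zip(votes, cols, rows, rads)]
        # well-supported candidates only, then the one closest to the tip
        # (vote ties prefer the larger radius)
        vmax = max(v for v, *_ in contained)
        short = [t for t in contained if t[0] >= 0.85 * vmax]
        short.sort(key=lambda t: (np.hypot(t[1] - tip[0], t[2] - tip[1]),
                                  -t[0], -t[3]))
        _, r0, c0, rad = short[0]
        out[name] = shp.Circle((r0, c0), rad)
    return out


def extract_hand_rois(t: ThermalImage, config: dict | None = None,
                      template: PalmTemplate | None = None) -> ExtractionResult:
    """Full hand cascade: segmentation to the 8 labelled hand ROIs.

    Stage failures yield a partial result: the report names the failed
    stage and any ROI labels that could not be extracted.
    """
    cfg = resolve(config)
    hand_cfg = cfg["hand"]
    if t.region != "hand":
        raise ValueError("image region must be 'hand'")
    if t.side not in ("left", "right"):
        raise ValueError("hand side must be 'left' or 'right'")
    if template is None:
        template = DEFAULT_PALM_TEMPLATE
    side_tag = "R" if t.side == "right" else "L"
    expected = [NAME_TO_LABEL[f"finger_{f}_{side_tag}"] for f in FINGERS] + \
               [NAME_TO_LABEL[f"{p}_{side_tag}"]
                for p in ("palm_thenar", "palm_center", "palm_hypothenar")]
    report = PipelineReport(region="hand")
    empty = ROISet([], image_ref=t.source_path, region="hand")

    try:
        mask = adaptive_threshold(
            t, offset=cfg["segmentation"]["thermal_offset"], config=cfg)
        mask = clean_mask(mask, k=1, config=cfg)
        report.record("segmentation", True)
    except ValueError as e:
        report.record("segmentation", False, str(e))
        report.missing_labels = expected
        return ExtractionResult(empty, report)

    try:
        prof = opening_profile(mask)
        params = VarianceDetectorParams(hand_cfg["variance_window"],
                                        hand_cfg["variance_factor"])
        r = finger_radius(prof, params)
        fingers, palm_arm = split_fingers(mask, r,
                                          hand_cfg["min_finger_area"])
        report.record("finger_split", True, f"radius={r}")
    except ValueError as e:
        report.record("finger_split", False, str(e))
        report.missing_labels = expected
        return ExtractionResult(empty, report)

    palm_centroid = np.argwhere(palm_arm.bits).mean(axis=0)
    try:
        lf = label_fingers(fingers, palm_centroid, t.side)
        report.record("finger_labelling", True)
    except ValueError as e:
        report.record("finger_labelling", False, str(e))
        report.missing_labels = expected
        return ExtractionResult(empty, report)

    rois: list[ROI] = []
    taken = np.zeros_like(mask.bits)

    def add(label: int, shape: shp.Shape, raster: np.ndarray) -> bool:
        m = raster & mask.bits & ~taken
        if not m.any():
            return False
        rois.append(ROI(label=label, shape=shape, mask=BinaryMask(m)))
        taken[m] = True
        return True

    circles = fingertip_circles(lf, palm_centroid,
                                hand_cfg["hough_radius_frac"])
    for f in FINGERS:
        lab = NAME_TO_LABEL[f"finger_{f}_{side_tag}"]
        c = circles[f]
        if c is None:
            report.missing_labels.append(lab)
            report.warn(f"no fingertip circle for {f}")
            continue
        raster = shp.rasterise(c, mask.bits.shape) & lf.fingers[f].mask
        if not add(lab, c, raster):
            report.missing_labels.append(lab)
    report.record("fingertips", len(report.missing_labels) == 0)

    try:
        anchors = palm_anchor_points(lf, palm_centroid)
        fitted = fit_palm_template(template, anchors, mask)
        for part, (s, m) in zip(("palm_thenar", "palm_center",
                                 "palm_hypothenar"), fitted):
            lab = NAME_TO_LABEL[f"{part}_{side_tag}"]
            if not add(lab, s, m):
                report.missing_labels.append(lab)
        report.record("palm_template", True)
    except (ValueError, RuntimeError) as e:
        report.record("palm_template", False, str(e))
        for part in ("palm_thenar", "palm_center", "palm_hypothenar"):
            report.missing_labels.append(NAME_TO_LABEL[f"{part}_{side_tag}"])

    rs = ROISet(rois, image_ref=t.source_path, region="hand")
    return ExtractionResult(rs, report, foreground=mask)
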