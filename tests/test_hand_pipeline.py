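"""The hand cascade: opening profile, drop detector, finger labelling,
palm template fit and fingertip circles."""
import numpy as np
import pytest
from scipy import ndimage

from thermoroi import shapes as shp
from thermoroi.evaluation import dice
from thermoroi.hand_pipeline import (DEFAULT_PALM_TEMPLATE, FingerBlob,
                                     LabelledFingers, OpeningProfile,
                                     VarianceDetectorParams,
                                     extract_hand_rois, finger_radius,
                                     fingertip_circles, fit_palm_template,
                                     label_fingers, opening_profile,
                                     palm_anchor_points, solve_affine_3pt,
                                     split_fingers)
from thermoroi.morpho import disc_footprint
from thermoroi.segmentation import adaptive_threshold, clean_mask
from thermoroi.thermal_io import BinaryMask, ThermalImage


# ---------------------------------------------------------------------------
# opening profile

def test_single_pixel_mask_vanishes_for_all_radii():
    m = np.zeros((9, 9), bool)
    m[4, 4] = True
    p = opening_profile(BinaryMask(m), r_max=4)
    assert np.all(p.areas == 0)


def test_disc_profile_matches_brute_morphology_and_extinction():
    m = np.zeros((40, 40), bool)
    rr, cc = np.mgrid[0:40, 0:40]
    m |= (rr - 20) ** 2 + (cc - 20) ** 2 <= 100   # disc radius 10
    p = opening_profile(BinaryMask(m), r_max=14)
    oracle = []
    for r in p.radii:
        fp = disc_footprint(int(r))
        er = ndimage.binary_erosion(m, structure=fp, border_value=0)
        op = ndimage.binary_dilation(er, structure=fp, border_value=0)
        from thermoroi.morpho import binary_opening_disc
        assert np.array_equal(binary_opening_disc(m, int(r)), op)
        oracle.append(op.sum())
    # profile = running-minimum envelope of the exact opening areas
    assert np.array_equal(p.areas, np.minimum.accumulate(oracle))
    assert np.all(p.areas[10:] == 0)              # gone past its own radius
    assert np.all(np.diff(p.areas) <= 0)


def test_hand_phantom_profile_has_drop_then_plateau(hand_phantom):
    mask = clean_mask(adaptive_threshold(hand_phantom.thermal, offset=0.1),
                      k=1)
    p = opening_profile(mask)
    assert np.all(np.diff(p.areas) <= 0)
    w = hand_phantom.meta["finger_halfwidth"]
    drop = p.areas[int(w) - 1] - p.areas[int(w) + 2]
    plateau = p.areas[int(w) + 3] - p.areas[int(w) + 9]
    assert drop > 5 * max(plateau, 1)             # sharp drop then plateau


# ---------------------------------------------------------------------------
# variance detector

def test_constant_profile_raises():
    p = OpeningProfile(np.arange(1, 41), np.full(40, 500.0))
    with pytest.raises(ValueError, match="no finger drop"):
        finger_radius(p)


def test_step_profile_detected_within_window_support():
    # A = 1000 for r < 5, 400 for r >= 5; hand-evaluated Eq. windows give
    # the first straddling window at r = 6, inside the support [3, 7]
    radii = np.arange(1, 41)
    p = OpeningProfile(radii, np.where(radii < 5, 1000.0, 400.0))
    r = finger_radius(p, VarianceDetectorParams(4, 5.0))
    assert r == 6
    assert 5 - 2 <= r <= 5 + 2


def test_phantom_finger_radius_near_true_halfwidth(hand_phantom):
    mask = clean_mask(adaptive_threshold(hand_phantom.thermal, offset=0.1),
                      k=1)
    w = hand_phantom.meta["finger_halfwidth"]
    r = finger_radius(opening_profile(mask))
    assert w <= r <= w + 2


# ---------------------------------------------------------------------------
# finger split + labelling

def test_split_fingers_set_algebra(hand_phantom):
    mask = clean_mask(adaptive_threshold(hand_phantom.thermal, offset=0.1),
                      k=1)
    r = finger_radius(opening_profile(mask))
    fingers, palm_arm = split_fingers(mask, r)
    assert not (fingers.bits & palm_arm.bits).any()
    assert np.all(mask.bits[fingers.bits])
    assert np.all(mask.bits[palm_arm.bits])
    _, n = ndimage.label(fingers.bits, structure=np.ones((3, 3), bool))
    assert n == 5


def test_split_without_protrusions_raises():
    m = np.zeros((40, 40), bool)
    m[10:30, 10:30] = True
    with pytest.raises(ValueError):
        split_fingers(BinaryMask(m), 3)


def _blob_at(angle_deg, centroid=(100.0, 100.0), dist=60.0, hw=(60, 60)):
    th = np.deg2rad(angle_deg)
    c = np.array([centroid[0] - dist * np.sin(th),
                  centroid[1] + dist * np.cos(th)])
    m = np.zeros((200, 200), bool)
    r0, c0 = int(round(c[0])), int(round(c[1]))
    m[r0 - 3:r0 + 4, c0 - 3:c0 + 4] = True
    return m


def _fingers_mask(angles):
    m = np.zeros((200, 200), bool)
    for a in angles:
        m |= _blob_at(a)
    return BinaryMask(m)


def exhaustive_widest_pair(angles):
    """Oracle: the pair subtending the largest angle at the centroid."""
    best, pair = -1, None
    for i in range(len(angles)):
        for j in range(i + 1, len(angles)):
            d = abs(angles[i] - angles[j]) % 360
            d = min(d, 360 - d)
            if d > best:
                best, pair = d, (angles[i], angles[j])
    return set(pair)


@pytest.mark.parametrize("rotate_by", [0.0, 37.0])
def test_label_fingers_angle_oracle_and_rotation_invariance(rotate_by):
    base = [-60.0, -30.0, 0.0, 30.0, 90.0]
    angles = [a + rotate_by for a in base]
    lf = label_fingers(_fingers_mask(angles), (100.0, 100.0), "right")
    centroid = np.array([100.0, 100.0])

    def ang_of(blob):
        d = blob.centroid - centroid
        return np.degrees(np.arctan2(-d[0], d[1]))

    thumb_a = ang_of(lf.fingers["thumb"])
    little_a = ang_of(lf.fingers["little"])
    assert {round(thumb_a), round(little_a)} == \
        {round(a) for a in exhaustive_widest_pair(angles)}
    # right hand: thumb at the anticlockwise end (largest base angle)
    assert thumb_a == pytest.approx(90.0 + rotate_by, abs=3.0)
    assert little_a == pytest.approx(-60.0 + rotate_by, abs=3.0)


def test_label_fingers_mirror_on_left_side():
    angles = [-60.0, -30.0, 0.0, 30.0, 90.0]
    lf = label_fingers(_fingers_mask(angles), (100.0, 100.0), "left")
    centroid = np.array([100.0, 100.0])
    d = lf.fingers["thumb"].centroid - centroid
    assert np.degrees(np.arctan2(-d[0], d[1])) == pytest.approx(-60.0,
                                                                abs=3.0)


# ---------------------------------------------------------------------------
# palm anchors + template

def test_anchor_on_rectangle_blob_boundary_walk_oracle():
    m = np.zeros((60, 30), bool)
    m[10:50, 8:12] = True                       # 4 x 40 vertical rectangle
    blob_mask = m
    pts = np.argwhere(blob_mask).astype(float)
    ctr = pts.mean(axis=0)
    blob = FingerBlob(blob_mask, ctr, np.array([1.0, 0.0]))
    lf = LabelledFingers({n: blob for n in
                          ("thumb", "index", "middle", "ring", "little")})
    palm_centroid = (80.0, 10.0)                # below the rectangle
    anchors = palm_anchor_points(lf, palm_centroid)
    # the axis-boundary hit nearer the centroid below is the bottom end
    assert anchors[0][0] == pytest.approx(49.0, abs=1.0)
    assert anchors[0][1] == pytest.approx(9.5, abs=1.0)


def test_anchor_on_circular_blob_lies_on_boundary():
    m = np.zeros((40, 40), bool)
    rr, cc = np.mgrid[0:40, 0:40]
    m |= (rr - 20) ** 2 + (cc - 20) ** 2 <= 81
    blob = FingerBlob(m, np.array([20.0, 20.0]), np.array([1.0, 0.0]))
    lf = LabelledFingers({n: blob for n in
                          ("thumb", "index", "middle", "ring", "little")})
    anchors = palm_anchor_points(lf, (60.0, 20.0))
    er = ndimage.binary_erosion(m, np.ones((3, 3), bool))
    boundary = np.argwhere(m & ~er)
    d = np.hypot(boundary[:, 0] - anchors[0][0],
                 boundary[:, 1] - anchors[0][1])
    assert d.min() <= 1.0


def test_affine_identity_translation_and_compose_solve():
    tmpl = DEFAULT_PALM_TEMPLATE
    same = fit_palm_template(tmpl, tmpl.anchor_points)
    for got, want in zip(same, tmpl.roi_shapes):
        assert np.allclose(got.vertex_array(), want.vertex_array())

    shifted = fit_palm_template(tmpl, tmpl.anchor_points + [10.0, 5.0])
    for got, want in zip(shifted, tmpl.roi_shapes):
        assert np.allclose(got.vertex_array(),
                           want.vertex_array() + [10.0, 5.0])

    th = np.deg2rad(23.0)
    lin = 1.3 * np.array([[np.cos(th), np.sin(th)],
                          [-np.sin(th), np.cos(th)]])
    true_mat = np.hstack([lin, np.array([[4.0], [-2.0]])])
    dst = tmpl.anchor_points @ lin.T + true_mat[:, 2]
    rec = solve_affine_3pt(tmpl.anchor_points, dst)
    assert np.allclose(rec, true_mat, atol=1e-9)


def test_collinear_anchor_triple_rejected():
    src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
    with pytest.raises(ValueError, match="collinear"):
        solve_affine_3pt(src, src)


def test_template_anchor_residual_below_micron(hand_phantom):
    anchors = np.array([[140.0, 120.0], [110.0, 140.0], [125.0, 190.0]])
    mat = solve_affine_3pt(DEFAULT_PALM_TEMPLATE.anchor_points, anchors)
    mapped = DEFAULT_PALM_TEMPLATE.anchor_points @ mat[:, :2].T + mat[:, 2]
    assert np.abs(mapped - anchors).max() < 1e-6


# ---------------------------------------------------------------------------
# fingertip circles

def brute_hough_circle(edges, radii):
    """Exhaustive accumulator: count edge pixels within 0.5 px of each
    candidate circle; best (votes/perimeter, then radius) wins."""
    pts = np.argwhere(edges)
    best = (-1.0, None)
    for r in radii:
        for cr in range(edges.shape[0]):
            for cc_ in range(edges.shape[1]):
                d = np.hypot(pts[:, 0] - cr, pts[:, 1] - cc_)
                votes = np.sum(np.abs(d - r) <= 0.5) / (2 * np.pi * r)
                if votes > best[0]:
                    best = (votes, (cr, cc_, r))
    return best[1]


def _capped_finger_blob():
    blob = np.zeros((80, 40), bool)
    blob[30:70, 15:25] = True                   # 10 px wide rectangle
    rr, cc = np.mgrid[0:80, 0:40]
    blob |= ((rr - 30) ** 2 + (cc - 19.5) ** 2 <= 25) & (rr <= 30)
    return blob


def test_toy_finger_circle_matches_cap_and_accumulator_oracle():
    blob = _capped_finger_blob()
    pts = np.argwhere(blob).astype(float)
    ctr = pts.mean(axis=0)
    cov = np.cov((pts - ctr).T)
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    lf = LabelledFingers({n: FingerBlob(blob, ctr, axis) for n in
                          ("thumb", "index", "middle", "ring", "little")})
    circ = fingertip_circles(lf, (69.0, 19.5))["thumb"]
    assert np.hypot(circ.center[0] - 30, circ.center[1] - 19.5) <= 2.0
    assert 4 <= circ.radius <= 6
    # independent brute-force accumulator on the toy edge set
    er = ndimage.binary_erosion(blob, np.ones((3, 3), bool), border_value=0)
    oracle = brute_hough_circle((blob & ~er)[:45], range(4, 7))
    assert np.hypot(oracle[0] - 30, oracle[1] - 19.5) <= 2.0


# ---------------------------------------------------------------------------
# end to end

def test_full_hand_extraction_recovers_truth(hand_phantom):
    res = extract_hand_rois(hand_phantom.thermal)
    assert res.report.failed_stage is None
    assert len(res.roi_set.rois) == 8
    truth = {r.label: r for r in hand_phantom.truth.rois}
    for r in res.roi_set.rois:
        assert dice(r.mask, truth[r.label].mask).coefficient >= 0.7


def test_left_hand_mirrors_labels(hand_phantom_left):
    res = extract_hand_rois(hand_phantom_left.thermal)
    assert len(res.roi_set.rois) == 8
    assert {r.label for r in res.roi_set.rois} == set(range(9, 17))
    truth = {r.label: r for r in hand_phantom_left.truth.rois}
    for r in res.roi_set.rois:
        assert dice(r.mask, truth[r.label].mask).coefficient >= 0.7


def test_blank_image_fails_at_segmentation():
    t = ThermalImage(np.full((64, 64), 22.0), region="hand", side="right")
    res = extract_hand_rois(t)
    assert res.report.failed_stage == "segmentation"
    assert res.roi_set.rois == []
    assert len(res.report.missing_labels) == 8
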