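"""Registration, alignment, toe closure and circle/quad placement."""
import numpy as np
import pytest
from scipy import ndimage

from thermoroi import shapes as shp
from thermoroi.evaluation import dice
from thermoroi.foot_pipeline import (AffineTransform, PlacementParams,
                                     ToeRowRef, WidthProfile,
                                     align_foot_vertical, bof_circle,
                                     extract_foot_rois, heel_circle,
                                     link_edge_endpoints, place_quads,
                                     quad_centers,
                                     register_visual_to_thermal,
                                     toe_regions, warp_visual,
                                     width_profile)
from thermoroi.geometry import compose_affine, invert_affine
from thermoroi.thermal_io import BinaryMask, ThermalImage, VisualImage


# ---------------------------------------------------------------------------
# registration

def test_identity_from_identical_triples():
    pts = [[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]
    T = register_visual_to_thermal(pts, pts)
    assert np.allclose(T.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-12)


def test_known_similarity_recovered_exactly():
    th = np.deg2rad(12.0)
    lin = 1.3 * np.array([[np.cos(th), np.sin(th)],
                          [-np.sin(th), np.cos(th)]])
    off = np.array([5.0, -3.0])
    src = np.array([[0.0, 0.0], [40.0, 10.0], [5.0, 35.0], [20.0, 20.0]])
    dst = src @ lin.T + off
    T = register_visual_to_thermal(src, dst)
    assert np.allclose(T.matrix[:, :2], lin, atol=1e-9)
    assert np.allclose(T.matrix[:, 2], off, atol=1e-9)
    # composing with the inverse gives the identity
    comp = compose_affine(T.matrix, invert_affine(T.matrix))
    assert np.allclose(comp, [[1, 0, 0], [0, 1, 0]], atol=1e-9)


def test_noisy_overdetermined_fit_matches_normal_equations():
    rng = np.random.default_rng(0)
    src = rng.uniform(0, 100, (6, 2))
    lin = np.array([[1.1, 0.2], [-0.1, 0.9]])
    dst = src @ lin.T + [3.0, 4.0] + rng.normal(0, 0.5, (6, 2))
    T = register_visual_to_thermal(src, dst)
    A = np.hstack([src, np.ones((6, 1))])
    oracle = np.linalg.solve(A.T @ A, A.T @ dst).T
    assert np.allclose(T.matrix, oracle, atol=1e-9)


def test_collinear_points_rejected():
    src = [[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]
    with pytest.raises(ValueError, match="collinear"):
        register_visual_to_thermal(src, src)


def test_warp_identity_and_integer_shift():
    rng = np.random.default_rng(1)
    v = VisualImage(rng.integers(0, 255, (30, 40, 3)).astype(np.uint8))
    ident = AffineTransform(np.array([[1.0, 0, 0], [0, 1.0, 0]]))
    assert np.array_equal(warp_visual(v, ident, (30, 40)).pixels, v.pixels)
    shift = AffineTransform(np.array([[1.0, 0, 5.0], [0, 1.0, 3.0]]))
    out = warp_visual(v, shift, (30, 40)).pixels
    assert np.array_equal(out[5:, 3:], v.pixels[:-5, :-3])


def test_warp_round_trip_close_on_smooth_image():
    rr, cc = np.mgrid[0:60, 0:80]
    smooth = (120 + 60 * np.sin(rr / 12.0) * np.cos(cc / 15.0)).astype(
        np.uint8)
    v = VisualImage(np.stack([smooth] * 3, axis=-1))
    th = np.deg2rad(7.0)
    lin = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    T = AffineTransform(np.hstack([lin, [[2.0], [1.0]]]))
    once = warp_visual(v, T, (60, 80))
    back = warp_visual(once, T.inverse(), (60, 80))
    interior = np.s_[15:45, 15:65]
    diff = np.abs(back.pixels[interior].astype(float)
                  - v.pixels[interior].astype(float))
    assert diff.mean() < 2.0


# ---------------------------------------------------------------------------
# vertical alignment

def _ellipse(h, w, center, semi, angle=0.0):
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    th = np.deg2rad(angle)
    rl = (rr - center[0]) * np.cos(th) - (cc - center[1]) * np.sin(th)
    cl = (rr - center[0]) * np.sin(th) + (cc - center[1]) * np.cos(th)
    return (rl / semi[0]) ** 2 + (cl / semi[1]) ** 2 <= 1.0


def test_vertical_ellipse_needs_no_rotation():
    m = BinaryMask(_ellipse(120, 120, (60, 60), (45, 20)))
    aligned, rot = align_foot_vertical(m)
    assert rot == pytest.approx(0.0, abs=0.5)


def test_rotated_ellipse_rotation_recovered():
    m0 = _ellipse(160, 160, (80, 80), (55, 22))
    from thermoroi.geometry import rotate_array
    m = BinaryMask(rotate_array(m0, 25.0, order=0))
    aligned, rot = align_foot_vertical(m)
    assert abs(abs(rot) - 25.0) < 0.5
    # covariance of the aligned mask is axis-aligned, rows dominant
    pts = np.argwhere(aligned.bits).astype(float)
    cov = np.cov((pts - pts.mean(axis=0)).T)
    assert abs(cov[0, 1]) / np.trace(cov) < 0.01
    assert cov[0, 0] >= cov[1, 1]


def test_isotropic_mask_rejected():
    m = BinaryMask(_ellipse(80, 80, (40, 40), (25, 25)))
    with pytest.raises(ValueError, match="dominant axis"):
        align_foot_vertical(m)


# ---------------------------------------------------------------------------
# placement arithmetic

def _rect_profile(width=100.0, rows=range(0, 150), center=50.0):
    rs = np.array(list(rows))
    return WidthProfile(rs, np.full(rs.size, width),
                        np.full(rs.size, center))


def test_circle_diameter_and_center_forced_by_width():
    wp = _rect_profile()
    circ = bof_circle(wp, ToeRowRef(0.0, 50.0),
                      PlacementParams(beta=0.3, tau=1000.0, alpha=0.25))
    assert circ.radius == pytest.approx(0.3 * 100 / 2)
    assert circ.center[1] == pytest.approx(50.0)


def test_scan_stops_at_first_row_within_tau():
    wp = _rect_profile(rows=range(0, 151))
    circ = bof_circle(wp, ToeRowRef(40.0, 50.0),
                      PlacementParams(beta=0.3, tau=60.0, alpha=0.25))
    assert circ.center[0] == pytest.approx(100.0)   # |100 - 40| == 60


def test_large_tau_stops_at_bottom_row():
    wp = _rect_profile(rows=range(0, 151))
    circ = bof_circle(wp, ToeRowRef(40.0, 50.0),
                      PlacementParams(beta=0.3, tau=1e6, alpha=0.25))
    assert circ.center[0] == pytest.approx(150.0)


def test_unreachable_tau_raises():
    wp = _rect_profile(rows=range(100, 151))
    with pytest.raises(ValueError, match="exhausted"):
        bof_circle(wp, ToeRowRef(0.0, 50.0),
                   PlacementParams(beta=0.3, tau=1.0, alpha=0.25))


def test_quad_centers_worked_case():
    q1, q2 = quad_centers(100.0, 50.0, PlacementParams(0.3, 60.0, 0.25))
    assert q1 == pytest.approx(50 - 15 - 6.25)      # 28.75
    assert q2 == pytest.approx(50 + 15 + 6.25)      # 71.25


def test_quad_moves_down_off_toe_overlap():
    foot = np.zeros((200, 120), bool)
    foot[0:200, 10:110] = True
    wp = width_profile(BinaryMask(foot))
    circ = shp.Circle((100.0, 60.0), 15.0)
    toe = np.zeros_like(foot)
    toe[80:104, 20:50] = True      # overlaps the q1 square by ~4 rows
    qp = place_quads(circ, wp, PlacementParams(0.3, 60.0, 0.25), [toe],
                     BinaryMask(foot))
    assert qp.q1 is not None
    raster = shp.rasterise(qp.q1, foot.shape)
    assert not (raster & toe).any()
    top_before = 100 - 0.25 * 100 / 2.0
    top_after = qp.q1.vertex_array()[:, 0].min()
    assert top_after >= top_before + 4 - 1e-9


def test_quad_clear_of_everything_is_untouched():
    foot = np.zeros((200, 120), bool)
    foot[0:200, 10:110] = True
    wp = width_profile(BinaryMask(foot))
    circ = shp.Circle((100.0, 60.0), 15.0)
    qp = place_quads(circ, wp, PlacementParams(0.3, 60.0, 0.25), [],
                     BinaryMask(foot))
    w_rect = 25.0
    v = qp.q1.vertex_array()
    assert v[:, 0].min() == pytest.approx(100 - w_rect / 2)
    assert np.mean(v[:, 1]) == pytest.approx(60 - 15 - 6.25)


# ---------------------------------------------------------------------------
# edge linking + toe regions

def test_parallel_chains_link_and_enclose():
    edges = np.zeros((40, 40), bool)
    edges[10:25, 10] = True
    edges[10:25, 20] = True
    contour = np.zeros_like(edges)
    contour[8, 8:23] = True          # a lid joining the two chain tops
    contour[8:10, 8] = True
    contour[8:10, 22] = True
    closed = link_edge_endpoints(BinaryMask(edges), BinaryMask(contour))
    # the bottom endpoints (24,10) and (24,20) are 10 px apart; each tip
    # links to its nearest foreign edgel, enclosing the area between the
    # chains and the lid
    assert closed.bits.any()
    lab, n = ndimage.label(closed.bits)
    assert n >= 1
    assert closed.bits[15, 15]


def test_closed_ring_input_unchanged():
    ring = np.zeros((30, 30), bool)
    rr, cc = np.mgrid[0:30, 0:30]
    d = np.hypot(rr - 15, cc - 15)
    ring |= (d >= 8) & (d <= 9)
    closed = link_edge_endpoints(BinaryMask(ring),
                                 BinaryMask(np.zeros_like(ring)))
    assert closed.bits[15, 15]
    assert not closed.bits[2, 2]


def test_toe_regions_keeps_five_largest_and_orders_by_side():
    closed = np.zeros((60, 200), bool)
    widths = [22, 20, 18, 16, 14, 6]
    col = 10
    for wdt in widths:
        closed[10:10 + wdt, col:col + wdt] = True
        col += wdt + 8
    named_r, _ = toe_regions(BinaryMask(closed), open_radius=1, side="right")
    named_l, _ = toe_regions(BinaryMask(closed), open_radius=1, side="left")
    assert [n for n, _ in named_r] == ["toe_1", "toe_2", "toe_3", "toe_4",
                                       "toe_5"]
    # the 6-px region is dropped; toe_1 is leftmost for right feet,
    # rightmost for left feet
    cols_r = [np.argwhere(m)[:, 1].mean() for _, m in named_r]
    cols_l = [np.argwhere(m)[:, 1].mean() for _, m in named_l]
    assert cols_r == sorted(cols_r)
    assert cols_l == sorted(cols_l, reverse=True)


# ---------------------------------------------------------------------------
# heel + end to end

def test_heel_anchor_found_at_warm_pad(foot_phantom):
    res = extract_foot_rois(foot_phantom.thermal, foot_phantom.visual,
                            *foot_phantom.landmarks)
    heel = res.roi_set.get(30)
    assert heel is not None
    pad = foot_phantom.meta["pad_center"]
    assert abs(heel.shape.center[0] - pad[0]) <= 3.0


def test_edge_free_thermal_raises_in_heel_stage():
    mask = np.zeros((60, 40), bool)
    mask[10:50, 10:30] = True
    flat = ThermalImage(np.full((60, 40), 24.0), region="foot", side="right")
    with pytest.raises(ValueError):
        heel_circle(flat, BinaryMask(mask), PlacementParams(0.3, 60.0, 0.25))


def test_full_foot_extraction_recovers_truth(foot_phantom):
    res = extract_foot_rois(foot_phantom.thermal, foot_phantom.visual,
                            *foot_phantom.landmarks)
    assert len(res.roi_set.rois) == 11
    truth = {r.label: r for r in foot_phantom.truth.rois}
    for r in res.roi_set.rois:
        assert dice(r.mask, truth[r.label].mask).coefficient >= 0.6
    # pairwise disjoint, zero background overlap
    fg = foot_phantom.meta["silhouette"]
    union = np.zeros_like(fg)
    for r in res.roi_set.rois:
        assert not (union & r.mask.bits).any()
        union |= r.mask.bits


def test_collinear_landmarks_fail_at_registration(foot_phantom):
    pts = [[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]
    res = extract_foot_rois(foot_phantom.thermal, foot_phantom.visual,
                            pts, pts)
    assert res.report.failed_stage == "registration"
    assert res.roi_set.rois == []
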