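"""Dice overlap, interrater tables, sign test and success tallies."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import combinations

from thermoroi import shapes as shp
from thermoroi.evaluation import (dice, pairwise_dice, sign_test,
                                  success_rate, success_tally,
                                  temperature_difference)
from thermoroi.thermal_io import ROI, BinaryMask, ROISet


def test_dice_identity_disjoint_and_shifted_square():
    a = np.zeros((30, 30), bool)
    a[5:15, 5:15] = True
    assert dice(a, a).coefficient == 1.0
    b = np.zeros_like(a)
    b[20:25, 20:25] = True
    assert dice(a, b).coefficient == 0.0
    shifted = np.zeros_like(a)
    shifted[5:15, 10:20] = True
    assert dice(a, shifted).coefficient == pytest.approx(0.5)


def test_dice_empty_conventions():
    e = np.zeros((5, 5), bool)
    f = e.copy()
    f[2, 2] = True
    assert dice(e, e).coefficient == 1.0
    assert dice(e, f).coefficient == 0.0


def test_dice_dimension_mismatch():
    with pytest.raises(ValueError, match="differ"):
        dice(np.zeros((3, 3), bool), np.zeros((3, 4), bool))


@settings(deadline=None, max_examples=50)
@given(st.integers(0, 2 ** 31 - 1))
def test_dice_symmetric_and_one_iff_equal(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((16, 16)) < 0.4
    b = rng.random((16, 16)) < 0.4
    assert dice(a, b).coefficient == dice(b, a).coefficient
    assert (dice(a, b).coefficient == 1.0) == np.array_equal(a, b)


def _mask_roi(label, bits):
    return ROI(label=label, shape=shp.Raster(bits), mask=BinaryMask(bits))


def _rater(labels_to_masks, region="shin"):
    return ROISet([_mask_roi(l, m) for l, m in labels_to_masks.items()],
                  region=region)


def test_identical_raters_all_means_one():
    bits = np.zeros((20, 20), bool)
    bits[3:9, 3:9] = True
    b2 = np.zeros_like(bits)
    b2[12:18, 12:18] = True
    r = _rater({39: bits, 40: b2})
    table, msgs = pairwise_dice([r, r])
    assert msgs == []
    assert np.allclose(table["mean"], 1.0)
    assert np.allclose(table["sd"], 0.0)


def test_three_raters_match_pair_enumeration_oracle():
    rng = np.random.default_rng(4)
    raters = []
    for _ in range(3):
        bits = np.zeros((20, 20), bool)
        r0, c0 = rng.integers(2, 8, 2)
        bits[r0:r0 + 8, c0:c0 + 8] = True
        raters.append(_rater({39: bits}))
    table, _ = pairwise_dice(raters)
    vals = [dice(a.get(39).mask, b.get(39).mask).coefficient
            for a, b in combinations(raters, 2)]
    row = table[(table["group"] == "shins")
                & (table["stratum"] == "human-human")]
    assert row["n"].iloc[0] == 3
    assert row["mean"].iloc[0] == pytest.approx(np.mean(vals))
    assert row["sd"].iloc[0] == pytest.approx(np.std(vals, ddof=1))


def test_missing_label_excluded_and_reported():
    bits = np.zeros((10, 10), bool)
    bits[2:6, 2:6] = True
    b2 = np.zeros_like(bits)
    b2[6:9, 6:9] = True
    full = ROISet([_mask_roi(39, bits), _mask_roi(40, b2)], region="shin")
    partial = _rater({39: bits})
    table, msgs = pairwise_dice([full, partial])
    assert any("label 40" in m for m in msgs)
    assert table["n"].sum() == 1


def test_temperature_difference_identical_and_offsets():
    alg = pd.DataFrame({"label": [39, 40], "mean_temp": [30.0, 31.0]})
    same = temperature_difference(alg, alg.copy())
    assert np.allclose(same["mean"], 0.0)
    human = pd.DataFrame({"label": [39, 40], "mean_temp": [30.1, 31.3]})
    out = temperature_difference(alg, human)
    assert out["mean"].iloc[0] == pytest.approx(0.2)


def test_temperature_difference_label_mismatch():
    alg = pd.DataFrame({"label": [39], "mean_temp": [30.0]})
    human = pd.DataFrame({"label": [40], "mean_temp": [30.0]})
    with pytest.raises(ValueError, match="mismatch"):
        temperature_difference(alg, human)


def exact_binomial_two_sided(k, n):
    """Enumeration oracle: sum of P(X = i) over i with P(i) <= P(k)."""
    from math import comb
    pk = comb(n, k) * 0.5 ** n
    return min(1.0, sum(comb(n, i) * 0.5 ** n for i in range(n + 1)
                        if comb(n, i) * 0.5 ** n <= pk + 1e-12))


def test_sign_test_all_below_tolerance():
    p = sign_test([0.1] * 10, tolerance=0.55)
    assert p == pytest.approx(2 * 0.5 ** 10, rel=1e-9)


def test_sign_test_balanced_and_single():
    assert sign_test([1.0] * 5 + [0.1] * 5, 0.55) == pytest.approx(1.0)
    assert sign_test([1.0], 0.55) == pytest.approx(1.0)


def test_sign_test_matches_enumeration_up_to_n30():
    for n in range(1, 31):
        for k in range(n + 1):
            d = [1.0] * k + [0.1] * (n - k)
            assert sign_test(d, 0.55) == pytest.approx(
                exact_binomial_two_sided(k, n), rel=1e-9), (n, k)


def test_sign_test_ties_dropped_and_all_ties_error():
    assert sign_test([0.55, 0.55, 1.0], 0.55) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="tie"):
        sign_test([0.55, 0.55], 0.55)


def test_success_rates_reproduce_printed_percentages():
    assert round(success_rate(759, 775), 1) == 97.9
    assert round(success_rate(437, 465)) == 94
    assert round(success_rate(1196, 1240), 1) == 96.5
    assert round(success_rate(796, 804)) == 99
    assert round(success_rate(663, 855), 1) == 77.5
    assert round(success_rate(378, 513), 1) == 73.7
    assert round(success_rate(408, 513), 1) == 79.5
    assert round(success_rate(1449, 1881)) == 77


def test_success_tally_counts_match_hand_tally():
    assessments = [(1, True), (2, True), (3, False),   # fingers
                   (6, True), (7, False),              # palms
                   (39, True), (40, True)]             # shins
    tally = success_tally(assessments)
    t = tally.table.set_index("group")
    assert t.loc["fingers", "correct"] == 2
    assert t.loc["fingers", "incorrect"] == 1
    assert t.loc["fingers", "rate"] == pytest.approx(100 * 2 / 3)
    assert t.loc["palms", "rate"] == pytest.approx(50.0)
    assert t.loc["overall", "total"] == 7
    assert t.loc["overall", "correct"] == 5


def test_zero_successes_rate_zero():
    tally = success_tally([(39, False)] * 4)
    assert tally.rate("shins") == 0.0
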