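"""Validation machinery: Dice overlap, interrater tables, sign test, tallies.

The Dice similarity coefficient between two regions A and B is

    DSC(A, B) = 2 |A ∩ B| / (|A| + |B|)

computed by exact integer pixel counting.  The empty-vs-empty pair is
defined as 1.0 (identical regions) and empty-vs-nonempty as 0.0.

Temperature agreement between raters is assessed with an exact binomial
sign test on the counts of absolute differences exceeding a tolerance
(default 0.55 degC, one quarter of the 2.2 degC clinical asymmetry
reference used for the diabetic foot).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .labels import LABEL_GROUPS
from .thermal_io import BinaryMask, ROISet

__all__ = ["DiceResult", "dice", "pairwise_dice", "temperature_difference",
           "sign_test", "success_tally", "SuccessTally"]


@dataclass(frozen=True)
class DiceResult:
    coefficient: float
    area_a: int
    area_b: int
    overlap: int
    label: int | None = None


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray,
         label: int | None = None) -> DiceResult:
    """Dice similarity coefficient of two equally sized binary masks."""
    a_bits = a.bits if isinstance(a, BinaryMask) else np.asarray(a, bool)
    b_bits = b.bits if isinstance(b, BinaryMask) else np.asarray(b, bool)
    if a_bits.shape != b_bits.shape:
        raise ValueError(f"mask shapes differ: {a_bits.shape} vs {b_bits.shape}")
    na, nb = int(a_bits.sum()), int(b_bits.sum())
    ov = int((a_bits & b_bits).sum())
    if na + nb == 0:
        coef = 1.0
    else:
        coef = 2.0 * ov / (na + nb)
    return DiceResult(coef, na, nb, ov, label)


def pairwise_dice(human_raters: list[ROISet],
                  algorithm: ROISet | None = None,
                  groups: dict[int, str] | None = None
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Per-group mean/SD of Dice over rater pairs, split into strata.

    ``human_raters`` are compared pairwise with each other (stratum
    ``human-human``) and, when an ``algorithm`` set is given, each human
    is compared with it (stratum ``algorithm-human``).  A label present in
    one set of a pair but not the other is excluded from that pair and
    reported in the returned message list.
    """
    if groups is None:
        groups = LABEL_GROUPS
    records, messages = [], []

    def compare(name_a, rs_a, name_b, rs_b, stratum):
        labels_a = {r.label for r in rs_a.rois}
        labels_b = {r.label for r in rs_b.rois}
        for lab in sorted(labels_a ^ labels_b):
            messages.append(
                f"label {lab} missing in one of ({name_a}, {name_b}); "
                "pair excluded")
        for lab in sorted(labels_a & labels_b):
            d = dice(rs_a.get(lab).mask, rs_b.get(lab).mask, label=lab)
            records.append({"group": groups.get(lab, "other"),
                            "stratum": stratum, "label": lab,
                            "dsc": d.coefficient})

    for (i, ra), (j, rb) in combinations(enumerate(human_raters), 2):
        compare(f"rater{i}", ra, f"rater{j}", rb, "human-human")
    if algorithm is not None:
        for i, ra in enumerate(human_raters):
            compare("algorithm", algorithm, f"rater{i}", ra, "algorithm-human")

    if not records:
        return (pd.DataFrame(columns=["group", "stratum", "n", "mean", "sd"]),
                messages)
    df = pd.DataFrame(records)
    table = (df.groupby(["group", "stratum"])["dsc"]
               .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
               .reset_index())
    table["sd"] = table["sd"].fillna(0.0)
    return table, messages


def temperature_difference(alg: pd.DataFrame, human: pd.DataFrame,
                           groups: dict[int, str] | None = None
                           ) -> pd.DataFrame:
    """Per-group mean/SD of |mean-temperature difference| between raters.

    Both inputs are temperature summaries (as from
    ``thermal_io.extract_temperatures``); rows are matched on label and a
    label present in only one summary raises.
    """
    if groups is None:
        groups = LABEL_GROUPS
    a = alg.set_index("label")["mean_temp"]
    h = human.set_index("label")["mean_temp"]
    if set(a.index) != set(h.index):
        raise ValueError(
            f"label mismatch: {sorted(set(a.index) ^ set(h.index))}")
    diffs = (a - h.reindex(a.index)).abs()
    df = pd.DataFrame({
        "group": [groups.get(l, "other") for l in diffs.index],
        "abs_diff": diffs.values,
        "label": diffs.index,
    })
    out = (df.groupby("group")["abs_diff"]
             .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
             .reset_index())
    out["sd"] = out["sd"].fillna(0.0)
    return out


def sign_test(differences, tolerance: float = 0.55,
              alternative: str = "two-sided") -> float:
    """Exact binomial sign test of |d_i| against a tolerance.

    Counts how many absolute differences exceed the tolerance; ties
    (|d_i| == tolerance) are dropped; the p-value is the exact binomial
    probability of the exceedance count under Binomial(n_eff, 1/2).
    ``alternative`` may be ``two-sided`` (default), ``greater`` or
    ``less`` (exceedances more / fewer than chance).
    """
    d = np.abs(np.asarray(list(differences), dtype=float))
    if d.size < 1:
        raise ValueError("need at least one difference")
    keep = d != tolerance
    n_eff = int(keep.sum())
    if n_eff == 0:
        raise ValueError("all differences tie with the tolerance; "
                         "sign test undefined")
    k = int((d[keep] > tolerance).sum())
    return float(stats.binomtest(k, n_eff, 0.5,
                                 alternative=alternative).pvalue)


@dataclass(frozen=True)
class SuccessTally:
    """Correct/incorrect ROI counts and percentage rates per group."""

    table: pd.DataFrame  # columns: group, correct, incorrect, total, rate

    def rate(self, group: str) -> float:
        row = self.table[self.table["group"] == group]
        if row.empty:
            raise KeyError(group)
        return float(row["rate"].iloc[0])


def success_tally(assessments: list[tuple[int, bool]] | list[tuple[str, bool]],
                  groups: dict[int, str] | None = None) -> SuccessTally:
    """Tally (label, correct?) assessments into per-group success rates.

    Labels may be integers (mapped through the canonical 44-label group
    table) or group-name strings.  Rates are ``100 * correct / total``;
    an ``overall`` row aggregates everything.
    """
    if groups is None:
        groups = LABEL_GROUPS
    rows = []
    for lab, ok in assessments:
        g = groups.get(lab, lab) if isinstance(lab, int) else lab
        rows.append({"group": g, "correct": bool(ok)})
    if not rows:
        return SuccessTally(pd.DataFrame(
            columns=["group", "correct", "incorrect", "total", "rate"]))
    df = pd.DataFrame(rows)
    per = (df.groupby("group")["correct"]
             .agg(correct="sum", total="size").reset_index())
    overall = pd.DataFrame([{"group": "overall",
                             "correct": per["correct"].sum(),
                             "total": per["total"].sum()}])
    per = pd.concat([per, overall], ignore_index=True)
    per["correct"] = per["correct"].astype(int)
    per["incorrect"] = per["total"] - per["correct"]
    per["rate"] = 100.0 * per["correct"] / per["total"]
    return SuccessTally(per[["group", "correct", "incorrect", "total", "rate"]])


def success_rate(correct: int, total: int) -> float:
    """Percentage rate 100 * correct / total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * correct / total
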