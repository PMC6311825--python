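"""Canonical enumeration of the 44 anatomical regions of interest.

Hands carry labels 1-16 (8 per hand: five fingertip discs and three palm
regions), feet 17-38 (11 per foot: five toes, a ball-of-foot circle with
two flanking quadrilaterals, and a heel circle with two flanking
quadrilaterals), shins 39-44 (3 per shin).  The right limb always takes
the lower label block.  Every label also belongs to one of six groups
used for reporting: fingers, palms, shins, toes, bof, heel.
"""
from __future__ import annotations

FINGERS = ("thumb", "index", "middle", "ring", "little")
TOES = ("toe_1", "toe_2", "toe_3", "toe_4", "toe_5")  # toe_1 = hallux
PALM_PARTS = ("palm_thenar", "palm_center", "palm_hypothenar")
SHIN_PARTS = ("shin_top", "shin_center", "shin_lower")
FOOT_DEEP = ("bof_circle", "bof_quad_1", "bof_quad_2",
             "heel_circle", "heel_quad_1", "heel_quad_2")

LABEL_NAMES: dict[int, str] = {}
LABEL_GROUPS: dict[int, str] = {}


def _add(start: int, names, side: str, group_of):
    for i, nm in enumerate(names):
        lab = start + i
        LABEL_NAMES[lab] = f"{nm}_{side}"
        LABEL_GROUPS[lab] = group_of(nm)


_add(1, [f"finger_{f}" for f in FINGERS], "R", lambda n: "fingers")
_add(6, PALM_PARTS, "R", lambda n: "palms")
_add(9, [f"finger_{f}" for f in FINGERS], "L", lambda n: "fingers")
_add(14, PALM_PARTS, "L", lambda n: "palms")
_add(17, TOES, "R", lambda n: "toes")
_add(22, TOES, "L", lambda n: "toes")
_add(27, FOOT_DEEP[:3], "R", lambda n: "bof")
_add(30, FOOT_DEEP[3:], "R", lambda n: "heel")
_add(33, FOOT_DEEP[:3], "L", lambda n: "bof")
_add(36, FOOT_DEEP[3:], "L", lambda n: "heel")
_add(39, SHIN_PARTS, "R", lambda n: "shins")
_add(42, SHIN_PARTS, "L", lambda n: "shins")

assert len(LABEL_NAMES) == 44

NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

#: Labels expected per (region, side) image.
REGION_LABELS: dict[tuple[str, str], tuple[int, ...]] = {
    ("hand", "right"): tuple(range(1, 9)),
    ("hand", "left"): tuple(range(9, 17)),
    ("foot", "right"): tuple(range(17, 22)) + tuple(range(27, 33)),
    ("foot", "left"): tuple(range(22, 27)) + tuple(range(33, 39)),
    ("shin", "both"): tuple(range(39, 45)),
    ("shin", "right"): tuple(range(39, 42)),
    ("shin", "left"): tuple(range(42, 45)),
}

#: Maximum ROI count per single image of each region.
MAX_ROIS = {"hand": 8, "shin": 6, "foot": 11}
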