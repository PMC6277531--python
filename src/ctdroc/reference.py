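"""Observed summary counts from the source multi-site screening-challenge cohort.

These published per-allergen counts (positive challenges / total challenges,
1,247 challenges in 427 multi-food-allergic participants across 11 foods plus
an excluded "other" category) serve two roles: calibration targets for the
synthetic cohort generator's defaults, and worked-example inputs whose
positive-challenge percentages the package recomputes exactly.
"""

from __future__ import annotations

import math

# food -> (positive challenges, total challenges)
CHALLENGE_COUNTS: dict[str, tuple[int, int]] = {
    "almond": (30, 73),
    "cashew": (151, 163),
    "egg": (63, 71),
    "hazelnut": (68, 102),
    "milk": (67, 77),
    "peanut": (347, 377),
    "pecan": (88, 95),
    "pistachio": (60, 60),
    "sesame": (30, 42),
    "walnut": (121, 138),
    "wheat": (13, 16),
    "other": (16, 33),
}

#: The 11 analyzed allergens, in reporting order ("other" rows are excluded
#: from analysis, mirroring the source cohort's data management).
ANALYSIS_FOODS: tuple[str, ...] = tuple(
    f for f in CHALLENGE_COUNTS if f != "other"
)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero (as printed
    percentages are)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def positive_percent(food: str) -> int:
    """Positive-challenge percentage for ``food``, recomputed from counts."""
    pos, tot = CHALLENGE_COUNTS[food]
    return round_half_up(100.0 * pos / tot)


def total_positive_percent() -> int:
    """Cohort-wide positive-challenge percentage over all categories."""
    pos = sum(p for p, _ in CHALLENGE_COUNTS.values())
    tot = sum(t for _, t in CHALLENGE_COUNTS.values())
    return round_half_up(100.0 * pos / tot)


def positive_fraction(food: str) -> float:
    pos, tot = CHALLENGE_COUNTS[food]
    return pos / tot
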