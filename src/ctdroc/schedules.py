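"""Escalating protein-dose schedules for oral food challenges.

A standardized screening challenge feeds increasing amounts of food protein
every 15 minutes until either a dose-related allergic reaction occurs or a
cumulative dose of at least 500 mg protein has been tolerated (a *negative*
challenge).  The cumulative tolerated dose (CTD) is the last cumulative dose
ingested without a dose-related adverse event.

Two concrete schedules ship as defaults: the generic ladder
2, 5, 20, 50, 100, 100, 100, 124 mg (cumulative 2..501 mg) and a
low-start variant beginning at 1 mg used for pistachio, where challenges
were restricted to already cashew-reactive participants for safety.
Alternative ladders can be registered per food.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEGATIVE_THRESHOLD_MG: float = 500.0

__all__ = [
    "DoseSchedule",
    "default_schedule",
    "GENERIC_SCHEDULE",
    "PISTACHIO_SCHEDULE",
    "NEGATIVE_THRESHOLD_MG",
]


@dataclass(frozen=True)
class DoseSchedule:
    """An ordered ladder of single protein doses (mg) with running totals.

    Attributes
    ----------
    id : str
        Schedule label, recorded on every simulated challenge row.
    increments : tuple of float
        Single-dose protein amounts in mg, in feeding order.
    negative_threshold : float
        Cumulative mg defining a tolerated (negative) challenge; 500 by
        default.
    """

    id: str
    increments: tuple[float, ...]
    negative_threshold: float = NEGATIVE_THRESHOLD_MG
    cumulative: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        inc = np.asarray(self.increments, dtype=float)
        if inc.size == 0 or np.any(inc <= 0):
            raise ValueError("increments must be non-empty and positive")
        cum = np.cumsum(inc)
        if cum[-1] < self.negative_threshold:
            raise ValueError(
                f"schedule {self.id!r} tops out at {cum[-1]} mg, below the "
                f"negative threshold of {self.negative_threshold} mg"
            )
        object.__setattr__(self, "cumulative", tuple(cum.tolist()))

    def ctd_for_latent_dose(self, eliciting_mg: float) -> tuple[str, float]:
        """Map a latent eliciting dose onto (outcome, CTD).

        The reaction occurs at the first scheduled cumulative dose that
        reaches ``eliciting_mg``; the CTD is the preceding cumulative dose
        (0 for a reaction at the first dose).  A latent dose beyond the
        negative threshold is a tolerated challenge censored at the
        threshold.
        """
        if eliciting_mg > self.negative_threshold:
            return "negative", self.negative_threshold
        cum = np.asarray(self.cumulative)
        k = int(np.searchsorted(cum, eliciting_mg, side="left"))
        return "positive", (0.0 if k == 0 else float(cum[k - 1]))


GENERIC_SCHEDULE = DoseSchedule("generic", (2, 5, 20, 50, 100, 100, 100, 124))
PISTACHIO_SCHEDULE = DoseSchedule(
    "pistachio_low_start", (1, 2, 5, 20, 50, 100, 100, 100, 123)
)

_REGISTRY: dict[str, DoseSchedule] = {"pistachio": PISTACHIO_SCHEDULE}


def default_schedule(food: str) -> DoseSchedule:
    """Return the dosing ladder used by default for ``food``.

    Pistachio gets the 1-mg low-start variant; every other (including
    unrecognized) food gets the generic ladder.
    """
    return _REGISTRY.get(str(food).strip().lower(), GENERIC_SCHEDULE)
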