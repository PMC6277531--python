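"""Dose-to-reaction cumulative incidence with right-censoring at 500 mg.

The "time" axis is the cumulative tolerated dose (mg of food protein): a
positive challenge contributes an event at its CTD, a negative challenge is
censored at 500 mg.  Estimation is the Kaplan-Meier product limit; tied event
doses (pervasive, because doses sit on a discrete ladder) decrement the risk
set simultaneously, and subjects censored at a dose remain at risk for events
at that same dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test

__all__ = ["SurvivalCurve", "LogrankResult", "km_curve", "logrank",
           "survival_at"]


@dataclass
class SurvivalCurve:
    """Product-limit estimate over the observed event doses.

    ``survival[k]`` is S(dose_grid[k]); S is 1 before the first event dose.
    ``median_ctd`` is the smallest event dose at which cumulative incidence
    reaches 0.5 (NaN if it never does).
    """

    dose_grid: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    median_ctd: float
    n: int

    def at(self, dose: float) -> float:
        """S(dose); 1 below the first event dose."""
        k = np.searchsorted(self.dose_grid, dose, side="right")
        return 1.0 if k == 0 else float(self.survival[k - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose_mg": self.dose_grid,
            "survival": self.survival,
            "at_risk": self.at_risk,
            "n_events": self.n_events,
            "n_censored": self.n_censored,
        })


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def km_curve(dose, event) -> SurvivalCurve:
    """Kaplan-Meier curve of reaction by cumulative dose for one stratum."""
    dose = np.asarray(dose, dtype=float)
    event = np.asarray(event, dtype=int)
    if dose.size == 0:
        raise ValueError("empty stratum")
    if np.any(dose < 0):
        raise ValueError("doses must be non-negative")

    times = np.unique(dose[event == 1])
    surv, risks, events_n, cens_n = [], [], [], []
    s = 1.0
    for t in times:
        n_risk = int(np.sum(dose >= t))
        d = int(np.sum((dose == t) & (event == 1)))
        c = int(np.sum((dose == t) & (event == 0)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        risks.append(n_risk)
        events_n.append(d)
        cens_n.append(c)

    surv_arr = np.asarray(surv)
    median = np.nan
    crossed = np.flatnonzero(1.0 - surv_arr >= 0.5)
    if crossed.size:
        median = float(times[crossed[0]])
    return SurvivalCurve(times, surv_arr, np.asarray(risks, dtype=int),
                         np.asarray(events_n, dtype=int),
                         np.asarray(cens_n, dtype=int), median, int(dose.size))


def survival_at(dose, event, t: float) -> float:
    """Product-limit S(t); NaN when follow-up in the stratum ends before t
    with subjects still at risk."""
    dose = np.asarray(dose, dtype=float)
    event = np.asarray(event, dtype=int)
    curve = km_curve(dose, event)
    last = dose.max()
    if t > last and curve.at(last) > 0.0:
        return np.nan
    return curve.at(t)


def logrank(doses, events, groups) -> LogrankResult:
    """k-sample log-rank test of equality of dose-to-reaction curves."""
    doses = np.asarray(doses, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least two strata")
    if events.sum() == 0:
        raise ValueError("no events in any stratum")
    res = multivariate_logrank_test(doses, groups, events)
    return LogrankResult(float(res.test_statistic), int(labels.size - 1),
                         float(res.p_value))
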