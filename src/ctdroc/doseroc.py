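"""Dose-dependent ROC analysis of biomarkers with censored dose-to-reaction.

The cumulative tolerated dose is treated as a right-censored "time"-to-event
axis and the ROC is the cumulative/dynamic variant at a dose horizon t
(500 mg by default): cases are challenges reacting by t, controls are
challenges still reaction-free beyond t,

    Se(c, t) = P(X > c | T <= t),      Sp(c, t) = P(X <= c | T > t).

Two estimators are provided:

* ``km_subset`` — product-limit curves within the marker-defined subsets
  combined with the marginal curve via Bayes' rule
  (Se = (1 - S(t | X > c)) P(X > c) / (1 - S(t))); used for threshold
  selection.  Subset-KM Se(c, t) is not guaranteed monotone in c; violations
  are clipped to monotone and counted.
* ``ipcw`` — inverse-probability-of-censoring weighting: each event at dose
  T_i <= t is weighted by 1 / G(T_i-), with G the product-limit estimate of
  the censoring distribution (reverse KM); used for the AUC.

With no censoring before the horizon both estimators collapse exactly to the
empirical binary-outcome ROC.  PPV and NPV at the chosen cutoff come from
the subset product-limit curves: PPV = 1 - S(t | X > c),
NPV = S(t | X <= c).  When a component is inestimable at the requested
horizon (e.g. a food with no challenge surviving beyond its last event dose)
the analysis steps down to the largest estimable event dose and records it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roc import ThresholdResult, _candidate_cutoffs, mann_whitney_auc
from .survival import SurvivalCurve, km_curve, logrank, survival_at

log = logging.getLogger(__name__)

__all__ = [
    "CtdRocResult", "ctd_sensitivity_specificity", "censoring_survival",
    "ipcw_auc", "ctd_roc_threshold", "stratified_km", "ctd_threshold_table",
]


@dataclass
class CtdRocResult:
    """Threshold, AUC, PPV/NPV and stratified log-rank at a dose horizon."""

    marker: str
    cutoff: float
    auc: float
    se_at_cut: float
    sp_at_cut: float
    youden: float
    horizon_mg: float
    effective_horizon_mg: float
    ppv: float
    npv: float
    estimator: str
    stratified_logrank_p: float
    n: int
    n_clipped: int = 0

    def as_threshold(self) -> ThresholdResult:
        return ThresholdResult(
            marker=self.marker, cutoff=self.cutoff, auc=self.auc,
            se_at_cut=self.se_at_cut, sp_at_cut=self.sp_at_cut,
            youden=self.youden, method="ctd",
            horizon_mg=self.effective_horizon_mg, ppv=self.ppv, npv=self.npv,
        )


def _case_ctrl(event: np.ndarray, dose: np.ndarray, t: float):
    """Cumulative/dynamic class masks at horizon t.

    Cases react by t; controls are reaction-free through t — strictly beyond
    t, or censored exactly at t (the 500 mg negatives when t = 500)."""
    case = (event == 1) & (dose <= t)
    ctrl = (dose > t) | ((event == 0) & (dose >= t))
    return case, ctrl


def censoring_survival(dose, event):
    """Reverse Kaplan-Meier: product-limit of the censoring distribution,
    treating censorings as events and events as censorings.  Censorings tied
    with events at a dose are taken to happen just after them, so G(T-) at an
    event dose excludes same-dose censorings."""
    dose = np.asarray(dose, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.all(event == 1):
        return None  # G identically 1
    return km_curve(dose, 1 - event)


def _g_minus(cens_curve, t: float) -> float:
    """G(t-): censoring survival just before t."""
    if cens_curve is None:
        return 1.0
    k = np.searchsorted(cens_curve.dose_grid, t, side="left")
    return 1.0 if k == 0 else float(cens_curve.survival[k - 1])


def ctd_sensitivity_specificity(
    marker, event, dose, cutoff: float, horizon: float,
    estimator: str = "km_subset",
) -> tuple[float, float]:
    """Cumulative/dynamic (Se, Sp) at one cutoff and dose horizon.

    Returns (nan, nan) when a required component is inestimable, which is
    the signal for the horizon-fallback rule upstream.
    """
    marker = np.asarray(marker, dtype=float)
    event = np.asarray(event, dtype=int)
    dose = np.asarray(dose, dtype=float)
    above = marker > cutoff

    if estimator == "km_subset":
        s_marg = survival_at(dose, event, horizon) if event.sum() else np.nan
        if not np.isfinite(s_marg) or s_marg in (0.0, 1.0):
            return np.nan, np.nan
        p_above = above.mean()
        se = sp = np.nan
        if above.any():
            s_above = _subset_surv(dose, event, above, horizon)
            if np.isfinite(s_above):
                se = (1.0 - s_above) * p_above / (1.0 - s_marg)
        else:
            se = 0.0
        if (~above).any():
            s_below = _subset_surv(dose, event, ~above, horizon)
            if np.isfinite(s_below):
                sp = s_below * (1.0 - p_above) / s_marg
        else:
            sp = 0.0
        return (float(np.clip(se, 0.0, 1.0)) if np.isfinite(se) else np.nan,
                float(np.clip(sp, 0.0, 1.0)) if np.isfinite(sp) else np.nan)

    if estimator == "ipcw":
        cens = censoring_survival(dose, event)
        case, ctrl = _case_ctrl(event, dose, horizon)
        if not case.any() or not ctrl.any():
            return np.nan, np.nan
        w = np.array([1.0 / _g_minus(cens, t) for t in dose[case]])
        se = float(np.sum(w * (marker[case] > cutoff)) / w.sum())
        sp = float(np.mean(marker[ctrl] <= cutoff))
        return se, sp

    raise ValueError(f"unknown estimator {estimator!r}")


def _subset_surv(dose, event, mask, t: float) -> float:
    sub_e = event[mask]
    if sub_e.sum() == 0:
        # no events in subset: S(t) = 1 wherever follow-up reaches t
        return 1.0 if dose[mask].max() >= t else np.nan
    return survival_at(dose[mask], sub_e, t)


def ipcw_auc(marker, event, dose, horizon: float) -> float:
    """Cumulative/dynamic AUC at the horizon with IPCW-weighted cases.

    Controls (T > horizon) share a single weight 1/G(horizon) which cancels,
    so only case weights 1/G(T_i-) enter.  With no censoring before the
    horizon this is exactly the Mann-Whitney AUC of marker against the
    binary event indicator.
    """
    marker = np.asarray(marker, dtype=float)
    event = np.asarray(event, dtype=int)
    dose = np.asarray(dose, dtype=float)
    case, ctrl = _case_ctrl(event, dose, horizon)
    if not case.any() or not ctrl.any():
        return np.nan
    cens = censoring_survival(dose, event)
    w = np.array([1.0 / _g_minus(cens, t) for t in dose[case]])
    return mann_whitney_auc(marker[case], marker[ctrl], pos_weights=w)


def _effective_horizon(marker, event, dose, horizon: float) -> float:
    """Largest dose <= horizon at which Se, Sp and AUC are estimable: needs
    at least one event at or below it and follow-up beyond it."""
    event_doses = np.unique(dose[event == 1])
    if event_doses.size == 0:
        raise ValueError("no events: dose-dependent ROC undefined")
    candidates = [horizon] + list(event_doses[::-1])
    for t in candidates:
        if t > horizon:
            continue
        case, ctrl = _case_ctrl(event, dose, t)
        s_marg = survival_at(dose, event, t)
        if case.any() and ctrl.any() and np.isfinite(s_marg) and 0.0 < s_marg < 1.0:
            return float(t)
    raise ValueError("dose-dependent ROC inestimable at every candidate horizon")


def ctd_roc_threshold(
    marker, event, dose, horizon: float = 500.0, marker_name: str = "marker"
) -> CtdRocResult:
    """Youden-optimal dose-dependent threshold with AUC/PPV/NPV at horizon.

    Threshold selection scans midpoint cutoffs with the subset product-limit
    estimator; the AUC uses IPCW weighting at the same horizon; PPV/NPV come
    from the subset curves at the chosen cutoff.  Falls back to the largest
    estimable event dose when the requested horizon is inestimable.
    """
    marker = np.asarray(marker, dtype=float)
    event = np.asarray(event, dtype=int)
    dose = np.asarray(dose, dtype=float)
    ok = np.isfinite(marker)
    marker, event, dose = marker[ok], event[ok], dose[ok]
    if marker.size == 0 or event.sum() == 0:
        raise ValueError("no events with non-missing marker")

    t_eff = _effective_horizon(marker, event, dose, horizon)
    cuts = _candidate_cutoffs(marker)
    se = np.full(cuts.size, np.nan)
    sp = np.full(cuts.size, np.nan)
    for i, c in enumerate(cuts):
        se[i], sp[i] = ctd_sensitivity_specificity(
            marker, event, dose, c, t_eff, estimator="km_subset"
        )
    # clip subset-KM non-monotonicity in c (known pathology); count it
    est = np.isfinite(se)
    n_clipped = int(np.sum(np.diff(se[est]) > 1e-12))
    if n_clipped:
        log.info("clipped %d non-monotone Se step(s) for %s", n_clipped,
                 marker_name)
    se[est] = np.minimum.accumulate(se[est])
    sp_f = np.where(np.isfinite(sp), sp, -np.inf)
    se_f = np.where(np.isfinite(se), se, -np.inf)
    j = se_f + sp_f - 1.0
    k = int(np.argmax(j))
    cutoff = float(cuts[k])

    auc = ipcw_auc(marker, event, dose, t_eff)
    above = marker > cutoff
    s_above = _subset_surv(dose, event, above, t_eff) if above.any() else np.nan
    s_below = _subset_surv(dose, event, ~above, t_eff) if (~above).any() else np.nan
    ppv = 1.0 - s_above if np.isfinite(s_above) else np.nan
    npv = s_below if np.isfinite(s_below) else np.nan

    if above.any() and (~above).any():
        p = stratified_km(marker, event, dose, cutoff)[2]
    else:
        p = np.nan
    return CtdRocResult(
        marker=marker_name, cutoff=cutoff, auc=float(auc),
        se_at_cut=float(se[k]), sp_at_cut=float(sp[k]), youden=float(j[k]),
        horizon_mg=float(horizon), effective_horizon_mg=t_eff,
        ppv=float(ppv), npv=float(npv), estimator="km_subset+ipcw",
        stratified_logrank_p=float(p), n=int(marker.size),
        n_clipped=n_clipped,
    )


def stratified_km(
    marker, event, dose, cutoff: float
) -> tuple[SurvivalCurve | None, SurvivalCurve | None, float]:
    """Dose-to-reaction curves above vs at-or-below the cutoff + log-rank p.

    An empty stratum yields (curve, None/None, nan) rather than an error,
    mirroring foods where threshold stratification failed.
    """
    marker = np.asarray(marker, dtype=float)
    event = np.asarray(event, dtype=int)
    dose = np.asarray(dose, dtype=float)
    above = marker > cutoff
    if not above.any() or not (~above).any():
        log.warning("stratification at cutoff %.3g leaves an empty stratum",
                    cutoff)
        curve = km_curve(dose, event)
        return (curve, None, np.nan) if above.any() else (None, curve, np.nan)
    res = logrank(dose, event, above.astype(int))
    return (km_curve(dose[above], event[above]),
            km_curve(dose[~above], event[~above]), res.p_value)


def ctd_threshold_table(
    records: pd.DataFrame, horizon: float = 500.0
) -> pd.DataFrame:
    """Per-food dose-dependent thresholds for each marker (Table-6 layout)."""
    from .roc import MARKERS

    rows = []
    for food, grp in records.groupby("food", sort=True):
        for marker, col in MARKERS.items():
            sub = grp[[col, "event", "dose_mg"]].dropna(subset=[col])
            try:
                res = ctd_roc_threshold(
                    sub[col], sub["event"], sub["dose_mg"], horizon, marker
                )
            except ValueError as exc:
                rows.append({"food": food, "marker": marker, "cutoff": np.nan,
                             "auc": np.nan, "ppv": np.nan, "npv": np.nan,
                             "effective_horizon_mg": np.nan,
                             "stratified_logrank_p": np.nan, "n": len(sub),
                             "skipped": str(exc)})
                continue
            rows.append({"food": food, "marker": marker, "cutoff": res.cutoff,
                         "auc": res.auc, "ppv": res.ppv, "npv": res.npv,
                         "effective_horizon_mg": res.effective_horizon_mg,
                         "stratified_logrank_p": res.stratified_logrank_p,
                         "n": res.n, "skipped": ""})
    return pd.DataFrame(rows)
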