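"""Binary-outcome ROC curves, Youden-index cutpoints, joint logistic models.

Biomarker thresholds are derived per food from the binary challenge outcome:
candidate cutoffs are midpoints between adjacent distinct observed marker
values (plus open endpoints), positivity means marker value strictly above
the cutoff, and the chosen cutoff maximizes Youden's J = Se + Sp - 1
(smallest cutoff on ties, which favours sensitivity).  AUC is the
tie-corrected Mann-Whitney statistic, identical to trapezoidal integration
of the empirical ROC polygon.

Joint models (SPT + sIgE, SPT + sIgE/tIgE) are maximum-likelihood logistic
fits; their apparent AUC is the Mann-Whitney AUC of the fitted linear
predictor against outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RocCurve", "ThresholdResult", "mann_whitney_auc", "empirical_roc",
    "youden_cutpoint", "fit_logistic_joint", "logistic_threshold_table",
    "MARKERS",
]

MARKERS = {"spt": "spt_net_mm", "sige": "sige_kul", "siger": "sige_ratio"}


@dataclass
class RocCurve:
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class ThresholdResult:
    marker: str
    cutoff: float
    auc: float
    se_at_cut: float
    sp_at_cut: float
    youden: float
    method: str = "logistic"
    horizon_mg: float | None = None
    ppv: float | None = None
    npv: float | None = None


def mann_whitney_auc(pos, neg, pos_weights=None) -> float:
    """P(random positive > random negative), ties counting 1/2.

    Optional non-negative weights on the positives (used by the
    inverse-censoring-weighted dose-dependent AUC).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.sort(np.asarray(neg, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one value in each class")
    lo = np.searchsorted(neg, pos, side="left")
    hi = np.searchsorted(neg, pos, side="right")
    per_pos = (lo + 0.5 * (hi - lo)) / neg.size
    if pos_weights is None:
        return float(per_pos.mean())
    w = np.asarray(pos_weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return float(np.sum(w * per_pos) / w.sum())


def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    v = np.unique(values)
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate([[v[0] - 1.0], mids, [v[-1] + 1.0]])


def empirical_roc(values, outcome) -> RocCurve:
    """ROC over midpoint cutoffs; Se(c) = P(X > c | pos), Sp(c) = P(X <= c | neg)."""
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if values.size != outcome.size:
        raise ValueError("length mismatch")
    ok = np.isfinite(values)
    values, outcome = values[ok], outcome[ok]
    pos = values[outcome == 1]
    neg = values[outcome == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both outcome classes with non-missing marker")
    cuts = _candidate_cutoffs(values)
    se = np.array([(pos > c).mean() for c in cuts])
    sp = np.array([(neg <= c).mean() for c in cuts])
    return RocCurve(cuts, se, sp, mann_whitney_auc(pos, neg),
                    int(pos.size), int(neg.size))


def youden_cutpoint(curve: RocCurve, marker: str = "marker") -> ThresholdResult:
    """Cutoff maximizing J = Se + Sp - 1; smallest cutoff on ties."""
    j = curve.sensitivity + curve.specificity - 1.0
    k = int(np.argmax(j))       # argmax returns the first (smallest) maximizer
    return ThresholdResult(
        marker=marker,
        cutoff=float(curve.cutoffs[k]),
        auc=curve.auc,
        se_at_cut=float(curve.sensitivity[k]),
        sp_at_cut=float(curve.specificity[k]),
        youden=float(j[k]),
    )


@dataclass
class LogisticJointFit:
    params: pd.Series
    linear_predictor: np.ndarray
    auc: float
    separated: bool
    n: int


def fit_logistic_joint(records: pd.DataFrame, markers: tuple[str, str],
                       outcome_col: str = "event") -> LogisticJointFit:
    """ML logistic fit of outcome on two markers (complete cases).

    Complete separation is flagged rather than fatal: the separating linear
    predictor still orders the classes perfectly, so the apparent AUC is 1.
    """
    cols = [MARKERS.get(m, m) for m in markers]
    df = records[cols + [outcome_col]].dropna()
    y = df[outcome_col].to_numpy(int)
    if y.min() == y.max():
        raise ValueError("single-class outcome")
    X = sm.add_constant(df[cols].to_numpy(float))
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = res.params
        except Exception:   # perfect separation raises in statsmodels
            separated = True
            res = sm.Logit(y, X).fit_regularized(alpha=1e-6, disp=0)
            params = res.params
    lp = X @ params
    fitted_p = 1.0 / (1.0 + np.exp(-lp))
    if not separated and (np.all(fitted_p[y == 1] > fitted_p[y == 0].max(initial=-np.inf))):
        separated = bool(np.max(np.abs(params[1:])) > 50)
    auc = mann_whitney_auc(lp[y == 1], lp[y == 0])
    return LogisticJointFit(
        pd.Series(params, index=["const"] + cols), np.asarray(lp), auc,
        separated, len(df),
    )


def logistic_threshold_table(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-food Youden cutoffs/AUCs for each marker plus the two joint AUCs.

    Foods without both outcome classes on a given marker's complete cases are
    skipped for that column (recorded with a reason).  Returns
    (single-marker table, joint-model table).
    """
    single_rows, joint_rows = [], []
    for food, grp in records.groupby("food", sort=True):
        for marker, col in MARKERS.items():
            sub = grp[[col, "event"]].dropna()
            if sub.empty or sub["event"].nunique() < 2:
                single_rows.append({
                    "food": food, "marker": marker, "cutoff": np.nan,
                    "auc": np.nan, "se": np.nan, "sp": np.nan,
                    "n": len(sub), "skipped": "single outcome class",
                })
                continue
            curve = empirical_roc(sub[col], sub["event"])
            res = youden_cutpoint(curve, marker)
            single_rows.append({
                "food": food, "marker": marker, "cutoff": res.cutoff,
                "auc": res.auc, "se": res.se_at_cut, "sp": res.sp_at_cut,
                "n": len(sub), "skipped": "",
            })
        for pair, label in ((("spt", "sige"), "spt+sige"),
                            (("spt", "siger"), "spt+siger")):
            try:
                fit = fit_logistic_joint(grp, pair)
            except ValueError as exc:
                joint_rows.append({"food": food, "model": label,
                                   "auc": np.nan, "n": 0, "skipped": str(exc)})
                continue
            row = {"food": food, "model": label, "auc": fit.auc, "n": fit.n,
                   "skipped": "separated" if fit.separated else ""}
            for name, val in fit.params.items():
                row[f"coef_{name}"] = val
            joint_rows.append(row)
    return pd.DataFrame(single_rows), pd.DataFrame(joint_rows)
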