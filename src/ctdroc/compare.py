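"""Bootstrap comparison of the two ROC paradigms, and threshold concordance.

The binary-outcome (logistic) AUC and the dose-dependent (IPCW at the 500 mg
horizon) AUC are recomputed on 1,000 bootstrap resamples of the challenge
records within each (food, marker); the percentile 95% CI of the paired
difference (dose-dependent minus logistic) decides whether the paradigms
differ.  Resampling is at the challenge-record level by default (an option
resamples participants instead, since repeat challenges share a
participant).

Concordance classifies each positive challenge as above/at-or-below the
dose-dependent thresholds of a marker pair; "accuracy" is the both-above
plus both-below percentage, pooled across foods for the overall agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseroc import ipcw_auc
from .roc import MARKERS, mann_whitney_auc

__all__ = ["BootstrapComparison", "bootstrap_auc_diff", "bootstrap_table",
           "concordance"]


@dataclass
class BootstrapComparison:
    food: str
    marker: str
    n_boot: int
    auc_logistic_mean: float
    auc_ctd_mean: float
    diff_ci_low: float
    diff_ci_high: float
    significant: bool
    n_redrawn: int
    unreliable: bool
    seed: int
    n: int


def _both_aucs(marker, event, dose, horizon):
    if event.min() == event.max():
        return None
    a_log = mann_whitney_auc(marker[event == 1], marker[event == 0])
    a_ctd = ipcw_auc(marker, event, dose, horizon)
    if not np.isfinite(a_ctd):
        return None
    return a_log, a_ctd


def bootstrap_auc_diff(
    records: pd.DataFrame,
    marker: str,
    n_boot: int = 1000,
    seed: int = 0,
    horizon: float = 500.0,
    resample_participants: bool = False,
) -> BootstrapComparison:
    """Percentile 95% CI of (dose-dependent - logistic) AUC for one food.

    Replicates where either AUC is inestimable (single outcome class, empty
    horizon class) are redrawn, with the redraw count reported; more redraws
    than replicates flags the comparison unreliable.
    """
    col = MARKERS.get(marker, marker)
    df = records.dropna(subset=[col])
    if len(df) < 10:
        raise ValueError(f"fewer than 10 records with non-missing {marker}")
    x = df[col].to_numpy(float)
    ev = df["event"].to_numpy(int)
    ds = df["dose_mg"].to_numpy(float)
    if ev.min() == ev.max():
        raise ValueError("single outcome class")
    food = str(df["food"].iloc[0]) if "food" in df else ""
    pid = df["participant_id"].to_numpy() if resample_participants else None

    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    a_logs = np.empty(n_boot)
    a_ctds = np.empty(n_boot)
    n = len(df)
    n_redrawn = 0
    for rep in range(n_boot):
        while True:
            if resample_participants:
                uniq = np.unique(pid)
                take = rng.choice(uniq, size=uniq.size, replace=True)
                idx = np.concatenate([np.flatnonzero(pid == p) for p in take])
            else:
                idx = rng.integers(0, n, n)
            res = _both_aucs(x[idx], ev[idx], ds[idx], horizon)
            if res is not None:
                break
            n_redrawn += 1
            if n_redrawn > 20 * n_boot:
                raise ValueError("bootstrap replicates almost never estimable")
        a_logs[rep], a_ctds[rep] = res
        diffs[rep] = res[1] - res[0]
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapComparison(
        food=food, marker=marker, n_boot=n_boot,
        auc_logistic_mean=float(a_logs.mean()),
        auc_ctd_mean=float(a_ctds.mean()),
        diff_ci_low=float(lo), diff_ci_high=float(hi),
        significant=bool(lo > 0.0 or hi < 0.0),
        n_redrawn=n_redrawn, unreliable=bool(n_redrawn > n_boot // 2),
        seed=seed, n=n,
    )


def bootstrap_table(
    records: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
    horizon: float = 500.0,
) -> pd.DataFrame:
    """bootstrap_auc_diff for every (food, marker) with enough data."""
    rows = []
    for i, (food, grp) in enumerate(records.groupby("food", sort=True)):
        for j, marker in enumerate(MARKERS):
            try:
                res = bootstrap_auc_diff(
                    grp, marker, n_boot=n_boot, seed=seed + 1000 * i + j,
                    horizon=horizon,
                )
            except ValueError as exc:
                rows.append({"food": food, "marker": marker, "skipped": str(exc)})
                continue
            d = res.__dict__.copy()
            d["skipped"] = ""
            rows.append(d)
    return pd.DataFrame(rows)


def concordance(
    positive_records: pd.DataFrame,
    thresholds: pd.DataFrame,
    marker_pair: tuple[str, str] = ("spt", "sige"),
) -> tuple[pd.DataFrame, float]:
    """Quadrant concordance of two marker thresholds among positive challenges.

    ``thresholds`` is a ctd_threshold_table-like frame (food, marker,
    cutoff).  Per food: percentages of records with both markers above, only
    the first above, only the second above, both at-or-below their cutoffs;
    accuracy = both-above% + both-below%.  Returns the per-food table and
    the record-pooled overall agreement.  "Above" is strictly greater-than.
    """
    m1, m2 = marker_pair
    c1 = MARKERS.get(m1, m1)
    c2 = MARKERS.get(m2, m2)
    cuts = thresholds.dropna(subset=["cutoff"]).set_index(["food", "marker"])["cutoff"]
    rows = []
    agree_n = 0
    total_n = 0
    df = positive_records.loc[positive_records["event"] == 1]
    for food, grp in df.groupby("food", sort=True):
        try:
            t1 = float(cuts.loc[(food, m1)])
            t2 = float(cuts.loc[(food, m2)])
        except KeyError:
            rows.append({"food": food, "n": 0,
                         "skipped": "threshold unavailable"})
            continue
        sub = grp[[c1, c2]].dropna()
        if sub.empty:
            rows.append({"food": food, "n": 0, "skipped": "no complete pairs"})
            continue
        a1 = sub[c1] > t1
        a2 = sub[c2] > t2
        n = len(sub)
        both_above = float((a1 & a2).mean() * 100)
        only_1 = float((a1 & ~a2).mean() * 100)
        only_2 = float((~a1 & a2).mean() * 100)
        both_below = float((~a1 & ~a2).mean() * 100)
        acc = both_above + both_below
        rows.append({
            "food": food, "n": n,
            f"both_above": both_above,
            f"{m1}_only_above": only_1,
            f"{m2}_only_above": only_2,
            "both_below": both_below,
            "accuracy": acc,
            "skipped": "",
        })
        agree_n += (a1 == a2).sum()
        total_n += n
    overall = 100.0 * agree_n / total_n if total_n else np.nan
    return pd.DataFrame(rows), float(overall)
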