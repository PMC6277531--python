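"""Cleaning, recoding and exclusion rules for raw challenge tables.

Ingests the three canonical CSV schemas (participants, biomarkers,
challenges) and produces one analysis record per retained challenge:

* placebo (oat) challenges dropped;
* challenges to foods outside the 11 analyzed allergens dropped ("other");
* positive challenges with CTD >= 500 mg recoded as negative (censored);
* negative challenges with CTD < 500 mg dropped as inconsistent;
* biomarkers attached per challenge using only measurements taken on or
  before the challenge date and no more than 12 months (365 days,
  boundary inclusive) earlier, most recent wins;
* saline control subtracted from raw SPT wheal, floored at 0 mm;
* sIgE clipped at 101 kU/L; sIgE/tIgE ratio computed after clipping;
* unknown ethnicity recoded missing; rare race labels pooled into "other".

Every rule contributes one row to a telescoping :class:`FilterLog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .reference import round_half_up

log = logging.getLogger(__name__)

__all__ = [
    "FilterLog",
    "truncate_sige",
    "net_spt",
    "select_biomarker",
    "recode_challenge",
    "apply_consort",
    "summarize",
    "CENSOR_DOSE_MG",
    "SIGE_CAP_KUL",
]

CENSOR_DOSE_MG = 500.0
SIGE_CAP_KUL = 101.0
BIOMARKER_WINDOW_DAYS = 365

PLACEBO_FOODS = ("oat",)
_POOL_RACE = {"native_hawaiian", "other", "not_reported"}
_MISSING_ETHNICITY = {"unknown", "not_reported", ""}


@dataclass
class FilterLog:
    """Ordered record of (rule, n in, n excluded, n out) for every step."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, rule: str, n_in: int, n_excluded: int) -> None:
        n_out = n_in - n_excluded
        if n_excluded < 0 or n_out < 0:
            raise ValueError(f"rule {rule!r}: inconsistent counts")
        self.steps.append((rule, n_in, n_excluded, n_out))

    def validate(self) -> None:
        """Counts must telescope: each rule's input is the previous output."""
        for prev, cur in zip(self.steps, self.steps[1:]):
            if cur[1] != prev[3]:
                raise ValueError(
                    f"filter log does not telescope at {cur[0]!r}: "
                    f"{cur[1]} != {prev[3]}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["rule", "n_in", "n_excluded", "n_out"]
        )


def truncate_sige(value: float) -> float:
    """Clip an sIgE measurement at the 101 kU/L reporting cap."""
    if value < 0:
        raise ValueError(f"sIgE must be non-negative, got {value}")
    return min(float(value), SIGE_CAP_KUL) if value > 100.0 else float(value)


def net_spt(raw_mm: float, saline_mm: float | None) -> float:
    """Saline-subtracted wheal diameter, floored at 0 mm."""
    if raw_mm < 0 or (saline_mm is not None and saline_mm < 0):
        raise ValueError("wheal diameters must be non-negative")
    if saline_mm is None or (isinstance(saline_mm, float) and np.isnan(saline_mm)):
        log.warning("missing saline control treated as 0 mm")
        saline_mm = 0.0
    return max(float(raw_mm) - float(saline_mm), 0.0)


def select_biomarker(
    measurements: pd.DataFrame,
    challenge_date: pd.Timestamp,
    window_days: int = BIOMARKER_WINDOW_DAYS,
) -> float | None:
    """Pick the value to attach to a challenge from dated measurements.

    Measurements after the challenge or more than ``window_days`` before it
    (boundary day kept) are discarded; among survivors the most recent wins.
    Returns None when nothing survives.
    """
    if measurements.empty:
        return None
    dates = pd.to_datetime(measurements["date"])
    challenge_date = pd.Timestamp(challenge_date)
    age = (challenge_date - dates).dt.days
    ok = (age >= 0) & (age <= window_days)
    if not ok.any():
        return None
    surv = measurements.loc[ok.values].assign(_d=dates[ok].values)
    surv = surv.sort_values("_d", kind="stable")
    return float(surv["value"].iloc[-1])


def recode_challenge(outcome: str, ctd_mg: float) -> tuple[int, float] | None:
    """Map a reported (outcome, CTD) onto (event, analysis dose) or exclusion.

    Positive below 500 mg -> event at the CTD; positive at >= 500 mg is
    recoded as a negative (censored) challenge; negative at >= 500 mg is
    censored at 500; negative below 500 mg is inconsistent and excluded
    (returns None).
    """
    if ctd_mg < 0:
        raise ValueError(f"negative CTD: {ctd_mg}")
    if outcome == "positive" and ctd_mg < CENSOR_DOSE_MG:
        return 1, float(ctd_mg)
    if ctd_mg >= CENSOR_DOSE_MG:
        return 0, CENSOR_DOSE_MG
    return None


def _biomarker_lookup(biomarkers: pd.DataFrame):
    if biomarkers.empty:
        return {}
    return {
        key: grp[["value", "date"]]
        for key, grp in biomarkers.groupby(["participant_id", "food", "kind"])
    }


def apply_consort(
    challenges: pd.DataFrame,
    biomarkers: pd.DataFrame,
    participants: pd.DataFrame,
    foods: tuple[str, ...] = reference.ANALYSIS_FOODS,
) -> tuple[pd.DataFrame, FilterLog]:
    """Run the full cleaning cascade; returns (analysis records, filter log).

    Records with absent biomarkers are retained (marker columns NaN) so that
    outcome-only analyses use every challenge; ROC stages drop missing
    markers per marker.
    """
    flog = FilterLog()
    df = challenges.copy()

    dup = df.duplicated(["participant_id", "food", "date"], keep=False)
    if dup.any():
        raise ValueError(
            "duplicate (participant, food, date) challenge rows:\n"
            f"{df.loc[dup, ['participant_id', 'food', 'date']].to_string(index=False)}"
        )

    n = len(df)
    is_placebo = df["food"].str.lower().isin(PLACEBO_FOODS)
    df = df.loc[~is_placebo]
    flog.add("placebo_challenges_excluded", n, int(is_placebo.sum()))

    n = len(df)
    is_other = ~df["food"].str.lower().isin([f.lower() for f in foods])
    df = df.loc[~is_other]
    flog.add("other_allergen_excluded", n, int(is_other.sum()))

    n = len(df)
    recoded = [recode_challenge(o, c) for o, c in zip(df["outcome"], df["ctd_mg"])]
    n_recoded_pos = sum(
        1 for (o, c) in zip(df["outcome"], df["ctd_mg"])
        if o == "positive" and c >= CENSOR_DOSE_MG
    )
    keep = [r is not None for r in recoded]
    df = df.loc[keep].copy()
    df["event"] = [r[0] for r in recoded if r is not None]
    df["dose_mg"] = [r[1] for r in recoded if r is not None]
    flog.add("positive_ctd_ge_500_recoded_negative", n, 0)
    flog.add("negative_ctd_lt_500_excluded", n, n - len(df))
    if n_recoded_pos:
        log.info("%d positive challenges at >= 500 mg recoded negative", n_recoded_pos)

    lookup = _biomarker_lookup(biomarkers)
    spt_net, sige_vals = [], []
    for row in df.itertuples():
        key = (row.participant_id, row.food)
        cdate = pd.Timestamp(row.date)
        raw = select_biomarker(
            lookup.get(key + ("spt_raw",), pd.DataFrame()), cdate
        )
        if raw is None:
            spt_net.append(np.nan)
        else:
            saline = select_biomarker(
                lookup.get(key + ("spt_saline",), pd.DataFrame()), cdate
            )
            spt_net.append(net_spt(raw, saline))
        sv = select_biomarker(lookup.get(key + ("sige",), pd.DataFrame()), cdate)
        sige_vals.append(np.nan if sv is None else truncate_sige(sv))
    df["spt_net_mm"] = spt_net
    df["sige_kul"] = sige_vals

    part = participants.copy()
    eth = part["ethnicity"].astype(str).str.lower()
    part["ethnicity"] = eth.where(~eth.isin(_MISSING_ETHNICITY), np.nan)
    race = part["race"].astype(str).str.lower()
    part["race"] = race.where(~race.isin(_POOL_RACE), "other")
    for col in ("fev1", "fev1_fvc"):
        if col not in part.columns:
            part[col] = np.nan

    df = df.merge(part, on="participant_id", how="left", validate="many_to_one")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["sige_ratio"] = np.where(
            df["tige_kul"] > 0, df["sige_kul"] / df["tige_kul"], np.nan
        )
    df["mono_allergic"] = (df["n_diagnosed_foods"] == 1).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["log_tige"] = np.where(df["tige_kul"] > 0,
                                  np.log(df["tige_kul"].where(df["tige_kul"] > 0)),
                                  np.nan)
    df["female"] = (df["sex"].astype(str).str.lower() == "female").astype(int)
    df["hispanic"] = np.where(
        df["ethnicity"].isna(), np.nan, (df["ethnicity"] == "hispanic").astype(float)
    )
    flog.add("final_analysis_records", len(df), 0)
    flog.validate()

    cols = ["participant_id", "food", "date", "event", "dose_mg",
            "spt_net_mm", "sige_kul", "tige_kul", "sige_ratio",
            "female", "hispanic", "race", "asthma", "rhinitis",
            "atopic_dermatitis", "age", "fev1", "fev1_fvc",
            "mono_allergic", "n_diagnosed_foods", "log_tige"]
    return df[cols].reset_index(drop=True), flog


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-food challenge and biomarker summary (plus a pooled total row).

    Positive percentages are integers rounded half-up as conventionally
    printed; SPT is summarized by mean (range), sIgE and the sIgE/tIgE ratio
    by median (range).
    """
    rows = []
    groups = list(records.groupby("food", sort=True))
    groups.append(("total", records))
    for food, grp in groups:
        n_tot = len(grp)
        n_pos = int(grp["event"].sum())
        pct = round_half_up(100.0 * n_pos / n_tot) if n_tot else 0
        spt = grp["spt_net_mm"].dropna()
        sige = grp["sige_kul"].dropna()
        ratio = grp["sige_ratio"].dropna()
        rows.append({
            "food": food,
            "n_positive": n_pos,
            "n_total": n_tot,
            "pct_positive": pct,
            "positive_ofcs": f"{n_pos}/{n_tot} ({pct})",
            "n_allergic_participants": grp.loc[grp["event"] == 1,
                                               "participant_id"].nunique(),
            "spt_n": len(spt),
            "spt_mean": spt.mean() if len(spt) else np.nan,
            "spt_min": spt.min() if len(spt) else np.nan,
            "spt_max": spt.max() if len(spt) else np.nan,
            "sige_n": len(sige),
            "sige_median": sige.median() if len(sige) else np.nan,
            "sige_min": sige.min() if len(sige) else np.nan,
            "sige_max": sige.max() if len(sige) else np.nan,
            "siger_n": len(ratio),
            "siger_median": ratio.median() if len(ratio) else np.nan,
            "siger_min": ratio.min() if len(ratio) else np.nan,
            "siger_max": ratio.max() if len(ratio) else np.nan,
        })
    return pd.DataFrame(rows)
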