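"""Synthetic multi-allergen oral-food-challenge cohorts with known ground truth.

The generator emulates a screening cohort of multi-food-allergic participants,
each challenged to a subset of 11 foods on an escalating protein-dose ladder
censored at 500 mg cumulative protein.  Its model:

* Each participant carries a Gaussian random effect ("frailty")
  ``b_i ~ N(0, frailty_sd^2)`` on the log10-dose scale, shared across all of
  their challenges, plus demographics and atopic-history flags drawn to match
  the source cohort's margins.
* For each challenged (participant, food) pair an ``allergic`` status is drawn;
  log-scale skin-prick-test (SPT) and specific-IgE (sIgE) markers come from a
  bivariate Normal whose mean is ``marker_mu_case`` for allergic and
  ``marker_mu_control`` for tolerant pairs (common SD, correlation ``rho``),
  so the ground-truth marker-vs-status AUC has the binormal closed form
  ``Phi(delta / (sd * sqrt(2)))``.
* The latent log10 eliciting dose is an accelerated-failure-time form
  ``D* = alpha_f - gamma * z + b_i + N(0, noise_sd^2)`` where ``z`` is the
  standardized mean of the two log-markers; the reaction lands on the first
  scheduled cumulative dose reaching ``10**D*``, and the cumulative tolerated
  dose (CTD) is the preceding rung (0 at the first rung).  Latent doses beyond
  500 mg yield negative challenges censored at 500.
* Per-food intercepts ``alpha_f`` are solved numerically so the expected
  positive fraction matches the observed cohort's per-food fractions
  (41-100%); challenge propensities match the observed per-food totals.

Raw sIgE is emitted untruncated (clipping at 101 kU/L is the cleaning stage's
job); SPT rows carry a raw wheal plus a saline negative-control wheal whose
difference is the net marker.  A configurable fraction of biomarker rows is
deliberately stale (>12 months old) or post-challenge so the cleaning-stage
window rules have work to do, and a configurable fraction of (participant,
food) pairs is re-challenged at a later date.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import reference
from .schedules import DoseSchedule, default_schedule

__all__ = ["SimConfig", "simulate_cohort", "true_binary_auc", "simulate_ph_frailty"]

_LOG10_THRESHOLD = np.log10(500.0)

_ETHNICITIES = ("non-hispanic", "hispanic", "unknown")
_ETHNICITY_P = (0.955, 0.03, 0.015)
_RACES = ("caucasian", "asian", "multiracial", "black", "other",
          "native_hawaiian", "not_reported")
_RACE_P = (0.60, 0.26, 0.10, 0.014, 0.01, 0.008, 0.008)


def _default_p_challenged() -> dict[str, float]:
    n = 427
    return {f: reference.CHALLENGE_COUNTS[f][1] / n for f in reference.ANALYSIS_FOODS}


def _default_p_allergic() -> dict[str, float]:
    return {f: reference.positive_fraction(f) for f in reference.ANALYSIS_FOODS}


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Defaults are calibrated once to the observed cohort: 427 participants,
    per-food challenge propensities proportional to observed challenge totals,
    per-food allergic probabilities equal to observed positive fractions, and
    a log-marker case-control separation of 1.5 (binormal AUC ~ 0.86).
    """

    n_participants: int = 427
    foods: tuple[str, ...] = reference.ANALYSIS_FOODS
    p_challenged: dict[str, float] = field(default_factory=_default_p_challenged)
    p_allergic_per_food: dict[str, float] = field(default_factory=_default_p_allergic)
    frailty_sd: float = 0.5
    marker_mu_case: float = 2.5
    marker_mu_control: float = 1.0
    marker_sd: float = 1.0
    rho: float = 0.6            # SPT-sIgE log-scale correlation
    gamma: float = 1.2          # slope of log10 eliciting dose on standardized marker
    alpha: dict[str, float] | None = None   # per-food intercepts; None -> calibrated
    noise_sd: float = 0.5
    tige_background: float = 400.0  # lognormal location of non-food total IgE, kU/L
    repeat_fraction: float = 0.10   # (participant, food) pairs re-challenged later
    p_stale_biomarker: float = 0.05  # biomarker sets outside the 12-month window
    p_fev1: float = 0.60
    seed: int = 0
    schedule_id: str = "default"

    def __post_init__(self) -> None:
        if not self.foods:
            raise ValueError("foods must be non-empty")
        for name in ("frailty_sd", "marker_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for f in self.foods:
            p = self.p_allergic_per_food.get(f, 0.5)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_allergic_per_food[{f!r}] outside [0, 1]")

    def schedule(self, food: str) -> DoseSchedule:
        return default_schedule(food)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def true_binary_auc(config: SimConfig, food: str | None = None) -> float:
    """Closed-form binormal AUC of either log-marker against allergic status.

    With case/control log-markers Normal(mu_case, sd^2) / Normal(mu_control,
    sd^2) the probability a random case exceeds a random control is
    ``Phi((mu_case - mu_control) / (sd * sqrt(2)))``; used as the ground
    truth in marker-recovery tests.
    """
    if config.marker_sd <= 0:
        raise ValueError("marker_sd must be > 0")
    delta = config.marker_mu_case - config.marker_mu_control
    return float(stats.norm.cdf(delta / (config.marker_sd * np.sqrt(2.0))))


def _calibrate_alpha(config: SimConfig, food: str) -> float:
    """Solve the per-food intercept so the expected positive fraction matches
    the configured allergic probability (capped at 0.995 for all-positive
    foods)."""
    p_target = min(max(config.p_allergic_per_food.get(food, 0.5), 0.02), 0.995)
    q = p_target
    mu_mid = 0.5 * (config.marker_mu_case + config.marker_mu_control)
    m_case = (config.marker_mu_case - mu_mid) / config.marker_sd
    m_ctrl = (config.marker_mu_control - mu_mid) / config.marker_sd
    # z is the mean of two standardized markers: var (1 + rho) / 2
    z_var = (1.0 + config.rho) / 2.0
    s = np.sqrt(config.gamma**2 * z_var + config.frailty_sd**2 + config.noise_sd**2)

    def p_pos(alpha: float) -> float:
        zc = (_LOG10_THRESHOLD - alpha + config.gamma * m_case) / s
        zt = (_LOG10_THRESHOLD - alpha + config.gamma * m_ctrl) / s
        return q * stats.norm.cdf(zc) + (1 - q) * stats.norm.cdf(zt)

    return float(optimize.brentq(lambda a: p_pos(a) - p_target, -15.0, 25.0))


def _alpha_map(config: SimConfig) -> dict[str, float]:
    if config.alpha is not None:
        return dict(config.alpha)
    return {f: _calibrate_alpha(config, f) for f in config.foods}


def _draw_date(rng: np.random.Generator) -> pd.Timestamp:
    # recruitment window of the emulated cohort
    start = pd.Timestamp("2010-09-01")
    return start + pd.Timedelta(days=int(rng.integers(0, 2007)))


def draw_markers(
    status: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw correlated (log-SPT-like, log-sIgE-like) markers given allergic
    status (1 = case)."""
    n = status.size
    mu = np.where(status == 1, config.marker_mu_case, config.marker_mu_control)
    cov = config.marker_sd**2 * np.array([[1.0, config.rho], [config.rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return mu + z[:, 0], mu + z[:, 1]


def simulate_cohort(
    config: SimConfig, return_truth: bool = False
) -> tuple[pd.DataFrame, ...]:
    """Generate (participants, biomarkers, challenges) tables.

    With ``return_truth=True`` a fourth table of latent ground truth
    (allergic status, standardized marker, latent log10 dose, frailty) is
    appended for validation work; it is never part of the canonical input
    schema.
    """
    rng = np.random.default_rng(config.seed)
    alphas = _alpha_map(config)
    n = config.n_participants

    pid = np.array([f"P{i:04d}" for i in range(n)])
    age = np.clip(np.round(rng.lognormal(np.log(9.0), 0.55, n)), 1, 54).astype(int)
    sex = rng.choice(["male", "female"], size=n, p=[0.61, 0.39])
    ethnicity = rng.choice(_ETHNICITIES, size=n, p=_ETHNICITY_P)
    race = rng.choice(_RACES, size=n, p=_RACE_P)
    asthma = rng.random(n) < 0.62
    rhinitis = rng.random(n) < 0.77
    ad = rng.random(n) < 0.73
    frailty = rng.normal(0.0, config.frailty_sd, n)
    fev1 = np.where(rng.random(n) < config.p_fev1,
                    np.round(rng.normal(95.0, 10.0, n), 1), np.nan)
    fev1_fvc = np.where(rng.random(n) < 0.45,
                        np.round(np.clip(rng.normal(0.85, 0.06, n), 0.4, 1.0), 3),
                        np.nan)

    challenged = {
        f: rng.random(n) < config.p_challenged.get(f, 0.3) for f in config.foods
    }
    # everyone is challenged to at least one food
    none_mask = ~np.logical_or.reduce(list(challenged.values()))
    if none_mask.any():
        fallback = np.full(n, -1)
        fallback[none_mask] = rng.choice(len(config.foods),
                                         size=int(none_mask.sum()))
        for j, f in enumerate(config.foods):
            challenged[f] |= fallback == j

    bio_rows: list[tuple] = []
    chal_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    sige_by_pid: dict[str, list[float]] = {p: [] for p in pid}
    n_challenged = np.zeros(n, dtype=int)

    for f in config.foods:
        idx = np.flatnonzero(challenged[f])
        if idx.size == 0:
            continue
        n_challenged[idx] += 1
        status = (rng.random(idx.size) < config.p_allergic_per_food.get(f, 0.5)).astype(int)
        y_spt, y_sige = draw_markers(status, config, rng)
        mu_mid = 0.5 * (config.marker_mu_case + config.marker_mu_control)
        z = ((y_spt - mu_mid) + (y_sige - mu_mid)) / (2.0 * config.marker_sd)
        schedule = config.schedule(f)

        # observable marker values in clinical units
        wheal = np.round(np.clip(np.exp(0.55 * y_spt + 1.2), 0.0, 40.0) * 2) / 2
        saline = np.round(rng.choice([0.0, 0.5, 1.0, 1.5, 2.0],
                                     size=idx.size,
                                     p=[0.55, 0.2, 0.15, 0.07, 0.03]) * 2) / 2
        sige = np.round(np.exp(y_sige), 2)

        for k, i in enumerate(idx):
            sige_by_pid[pid[i]].append(float(sige[k]))
            n_rounds = 2 if rng.random() < config.repeat_fraction else 1
            date0 = _draw_date(rng)
            for r in range(n_rounds):
                date = date0 + pd.Timedelta(days=int(r * rng.integers(60, 400)))
                dstar = (alphas[f] - config.gamma * z[k] + frailty[i]
                         + rng.normal(0.0, config.noise_sd))
                while not np.isfinite(dstar):  # pragma: no cover
                    dstar = (alphas[f] - config.gamma * z[k] + frailty[i]
                             + rng.normal(0.0, config.noise_sd))
                outcome, ctd = schedule.ctd_for_latent_dose(10.0**dstar)
                chal_rows.append((pid[i], f, date.date().isoformat(), outcome,
                                  ctd, schedule.id))
                # one biomarker set per challenge, usually inside the window
                if rng.random() < config.p_stale_biomarker:
                    offset = int(rng.choice([-1, 1])
                                 * rng.integers(380, 700))
                else:
                    offset = int(rng.integers(10, 300))
                bdate = (date - pd.Timedelta(days=offset)).date().isoformat()
                bio_rows.append((pid[i], f, "spt_raw", float(wheal[k] + saline[k]), bdate))
                bio_rows.append((pid[i], f, "spt_saline", float(saline[k]), bdate))
                bio_rows.append((pid[i], f, "sige", float(sige[k]), bdate))
                truth_rows.append((pid[i], f, date.date().isoformat(),
                                   int(status[k]), float(z[k]), float(dstar),
                                   float(frailty[i])))

    tige = np.array([
        sum(sige_by_pid[p]) for p in pid
    ]) + np.round(rng.lognormal(np.log(config.tige_background), 0.7, n), 1)
    n_diag = np.maximum(1, n_challenged + rng.poisson(2.5, n)).astype(int)

    participants = pd.DataFrame({
        "participant_id": pid,
        "age": age,
        "sex": sex,
        "ethnicity": ethnicity,
        "race": race,
        "asthma": asthma.astype(int),
        "rhinitis": rhinitis.astype(int),
        "atopic_dermatitis": ad.astype(int),
        "n_diagnosed_foods": n_diag,
        "tige_kul": np.round(tige, 1),
        "fev1": fev1,
        "fev1_fvc": fev1_fvc,
    })
    biomarkers = pd.DataFrame(
        bio_rows, columns=["participant_id", "food", "kind", "value", "date"]
    )
    challenges = pd.DataFrame(
        chal_rows,
        columns=["participant_id", "food", "date", "outcome", "ctd_mg", "schedule_id"],
    )
    out: tuple[pd.DataFrame, ...] = (participants, biomarkers, challenges)
    if return_truth:
        truth = pd.DataFrame(
            truth_rows,
            columns=["participant_id", "food", "date", "allergic", "z",
                     "log10_dose", "frailty"],
        )
        out = out + (truth,)
    return out


def simulate_ph_frailty(
    n_participants: int = 500,
    challenges_per: int = 4,
    log_hr: float = 0.5,
    frailty_sd: float = 0.5,
    censor_at: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Proportional-hazards validation generator for the frailty Cox fitter.

    Event times are exponential with rate ``exp(log_hr * x + b_i)`` for a
    balanced binary covariate ``x`` and participant frailty
    ``b_i ~ N(0, frailty_sd^2)``, administratively censored at ``censor_at``.
    Unlike the cohort generator this is exactly the model the fitter assumes,
    so it gives an unbiased recovery target for (log_hr, frailty_sd^2).
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, frailty_sd, n_participants)
    rows = []
    for i in range(n_participants):
        x = rng.integers(0, 2, challenges_per)
        t = rng.exponential(1.0 / np.exp(log_hr * x + b[i]))
        for j in range(challenges_per):
            tt = min(t[j], censor_at)
            rows.append((f"P{i:04d}", float(tt), int(t[j] <= censor_at), int(x[j])))
    return pd.DataFrame(rows, columns=["participant_id", "dose_mg", "event", "x"])
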