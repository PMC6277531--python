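import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized simulated cohort shared by read-only tests."""
    from ctdroc.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(n_participants=250, seed=42)
    participants, biomarkers, challenges = simulate_cohort(cfg)
    return cfg, participants, biomarkers, challenges


@pytest.fixture(scope="session")
def records(cohort):
    from ctdroc.cleaning import apply_consort

    _, participants, biomarkers, challenges = cohort
    recs, _ = apply_consort(challenges, biomarkers, participants)
    return recs


@pytest.fixture
def toy_consort():
    """Six raw challenges: one placebo (oat), one unanalyzed allergen, one
    inconsistent negative below 500 mg, three retained."""
    challenges = pd.DataFrame({
        "participant_id": ["P1", "P1", "P2", "P2", "P3", "P3"],
        "food": ["peanut", "oat", "kiwi", "milk", "peanut", "egg"],
        "date": ["2015-01-10"] * 6,
        "outcome": ["positive", "positive", "positive", "negative",
                    "negative", "positive"],
        "ctd_mg": [77.0, 27.0, 7.0, 500.0, 377.0, 2.0],
        "schedule_id": ["generic"] * 6,
    })
    biomarkers = pd.DataFrame({
        "participant_id": ["P1", "P1", "P1"],
        "food": ["peanut"] * 3,
        "kind": ["spt_raw", "spt_saline", "sige"],
        "value": [10.0, 2.0, 150.0],
        "date": ["2014-11-01"] * 3,
    })
    participants = pd.DataFrame({
        "participant_id": ["P1", "P2", "P3"],
        "age": [9, 12, 7],
        "sex": ["male", "female", "male"],
        "ethnicity": ["non-hispanic", "unknown", "hispanic"],
        "race": ["caucasian", "native_hawaiian", "asian"],
        "asthma": [1, 0, 1],
        "rhinitis": [1, 1, 0],
        "atopic_dermatitis": [0, 1, 1],
        "n_diagnosed_foods": [5, 1, 3],
        "tige_kul": [500.0, 300.0, 0.0],
    })
    return challenges, biomarkers, participants


def km_oracle(dose, event):
    """Brute-force product-limit: S(t) from its definition, by counting."""
    dose = np.asarray(dose, float)
    event = np.asarray(event, int)
    times = sorted(set(dose[event == 1]))
    out = {}
    s = 1.0
    for t in times:
        n_risk = sum(1 for d in dose if d >= t)
        d_t = sum(1 for d, e in zip(dose, event) if d == t and e == 1)
        s = s * (1 - d_t / n_risk)
        out[t] = s
    return out


def logrank_oracle(dose, event, group):
    """Two-sample log-rank from the 2x2 tables at each event time."""
    from scipy import stats

    dose = np.asarray(dose, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    g1 = np.unique(group)[1]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(dose[event == 1])):
        at_risk = dose >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == g1)).sum()
        d = ((dose == t) & (event == 1)).sum()
        d1 = ((dose == t) & (event == 1) & (group == g1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return np.nan, np.nan
    stat = o_minus_e**2 / var
    return stat, 1 - stats.chi2.cdf(stat, 1)


def partial_loglik_oracle(dose, event, x, beta):
    """Term-by-term Breslow partial log-likelihood with python loops."""
    n = len(dose)
    ll = 0.0
    for t in sorted(set(d for d, e in zip(dose, event) if e == 1)):
        d_t = [i for i in range(n) if dose[i] == t and event[i] == 1]
        risk = [i for i in range(n) if dose[i] >= t]
        denom = sum(np.exp(beta * x[i]) for i in risk)
        for i in d_t:
            ll += beta * x[i] - np.log(denom)
    return ll


def youden_oracle(values, outcome):
    """Exhaustive scan of all midpoint cutoffs, smallest max-J cutoff."""
    values = np.asarray(values, float)
    outcome = np.asarray(outcome, int)
    pos = values[outcome == 1]
    neg = values[outcome == 0]
    v = np.unique(values)
    cuts = [v[0] - 1] + [(a + b) / 2 for a, b in zip(v[:-1], v[1:])] + [v[-1] + 1]
    best = None
    for c in cuts:
        se = np.mean(pos > c)
        sp = np.mean(neg <= c)
        j = se + sp - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c, se, sp)
    return best
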