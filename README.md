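# ctdroc

Dose-to-reaction analysis of standardized oral food challenges (OFCs):
biomarker thresholds that account for *how much* allergen a patient
tolerated, not just whether they reacted.

In a screening OFC, food protein is fed in escalating doses (typically
2, 5, 20, 50, 100, 100, 100, 124 mg) until a dose-related allergic reaction
occurs or at least 500 mg cumulative protein is tolerated. The **cumulative
tolerated dose (CTD)** — the last cumulative dose ingested without a
reaction — makes the outcome a right-censored "time"-to-event on a dose
axis: a positive challenge is an event at its CTD, a negative one is
censored at 500 mg. `ctdroc` is for biostatisticians and allergy
researchers who want to exploit that structure when evaluating skin prick
tests (SPT), specific IgE (sIgE) and the sIgE/total-IgE ratio (sIgEr) as
predictors of challenge outcome.

## What it computes

* **Cleaning** — the data-management cascade for raw challenge tables:
  placebo and off-panel allergen exclusion, CTD-based outcome recoding,
  12-month biomarker windows with most-recent-wins selection,
  saline-subtracted SPT, sIgE capping at 101 kU/L, and a telescoping
  filter log.
* **Dose-to-reaction survival** — per-food Kaplan-Meier cumulative
  incidence over dose, median CTD, log-rank tests.
* **Frailty Cox models** — univariable associations of clinical features
  with outcome, `h_ij(d) = h0(d) exp(x_ij'β + b_i)`, with a Gaussian
  random intercept `b_i ~ N(0, σ²)` per participant and fixed adjustment
  for challenge food; hazard ratios with Wald 95% CIs; penalized partial
  likelihood with a Laplace profile over σ².
* **Logistic ROC thresholds** — per-food Youden-index cutoffs
  (J = Se + Sp − 1 over midpoint cutoffs), Mann-Whitney AUCs, and joint
  two-marker logistic models.
* **CTD-dependent ROC thresholds** — the cumulative/dynamic
  time-dependent ROC on the dose axis at a 500 mg horizon: cases react by
  the horizon, controls are reaction-free through it;
  `Se(c,t) = P(X > c | T ≤ t)`, `Sp(c,t) = P(X ≤ c | T > t)`. Thresholds
  from subset product-limit estimates, AUC from IPCW weighting, PPV/NPV
  from the above/below-threshold survival curves, with automatic fallback
  to a lower horizon when 500 mg is inestimable.
* **Method comparison** — 1,000-replicate bootstrap CIs of the
  (dose-dependent − logistic) AUC difference, and quadrant concordance of
  marker-pair thresholds among positive challenges.
* **Synthetic cohorts** — a calibrated generator with known ground truth
  (binormal marker structure, per-participant frailty, latent eliciting
  doses on the schedule ladder) so every stage is testable end to end.

See `docs/methods.md` for estimators, conventions and limitations.

## Worked example

```python
from ctdroc import (SimConfig, simulate_cohort, apply_consort,
                    ctd_threshold_table)

participants, biomarkers, challenges = simulate_cohort(
    SimConfig(n_participants=200, seed=7))
records, flog = apply_consort(challenges, biomarkers, participants)
print(len(records), int(records.event.sum()))

tab = ctd_threshold_table(records, horizon=500.0)
print(tab[tab.marker == "spt"]
      [["food", "cutoff", "auc", "ppv", "npv", "effective_horizon_mg"]])
```

prints (abridged):

```
637 533
     food  cutoff   auc   ppv   npv  effective_horizon_mg
   almond   14.75 0.971 1.000 0.944                 500.0
   cashew    7.75 0.925 0.984 0.435                 500.0
   peanut   10.25 0.912 0.991 0.319                 500.0
pistachio    4.00 1.000 1.000 1.000                   8.0
```

637 challenges survive cleaning, 533 of them positive. Each row gives a
food's SPT threshold in mm: a cashew SPT above 7.75 mm predicts a reaction
before 500 mg with probability 0.984 (PPV), while an SPT at or below it
gives a 0.435 probability of tolerating the full dose (NPV); the AUC is the
IPCW-weighted discrimination at the horizon. Pistachio — every challenge
positive in this draw — is inestimable at 500 mg and reports its threshold
at the largest estimable dose (8 mg), mirroring how all-positive foods
behave in real cohorts.

The `examples/` directory holds one short script per capability
(simulation, cleaning, survival, frailty Cox, logistic ROC, CTD ROC,
method comparison); each prints its results with a line on what they mean.
A thin CLI wraps the pipeline:

```sh
ctdroc all --seed 7 --out report/          # simulate + full report
ctdroc simulate --seed 7 --out data/
ctdroc clean --input data/ --out clean/
ctdroc roc --input clean/ --method ctd --out roc/
```

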