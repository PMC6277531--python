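# Methods

`ctdroc` analyzes standardized screening oral food challenges (OFCs) in
which food protein is fed in escalating doses until a dose-related allergic
reaction occurs or a cumulative dose of at least 500 mg has been tolerated.
The cumulative tolerated dose (CTD) — the last cumulative dose ingested
without a reaction — is the package's central quantity: a positive
challenge is an *event* at its CTD, a negative challenge is *right-censored
at 500 mg*. This note records the models, estimators, numerical choices and
known limitations.

## Dose schedules

The default ladder feeds 2, 5, 20, 50, 100, 100, 100, 124 mg of protein
(cumulative 2, 7, 27, 77, 177, 277, 377, 501 mg); pistachio uses a
low-start variant beginning at 1 mg, reflecting the practice of challenging
only already cashew-reactive patients to pistachio. Ladders are pluggable
per food; the only hard requirement is that the final cumulative dose
reaches the 500 mg negative threshold. The generic ladder's printed
increments sum to 501 mg; we keep 501 as the top rung with 500 as the
negative threshold, so a latent eliciting dose in (500, 501] still counts
as a tolerated challenge.

## Cleaning rules

The cleaning cascade (`ctdroc.cleaning.apply_consort`) applies, in order:
placebo (oat) challenges dropped; challenges to foods outside the 11
analyzed allergens dropped; positive challenges with CTD ≥ 500 mg recoded
as negative (they tolerated the analysis dose range); negative challenges
with CTD < 500 mg dropped as internally inconsistent. Biomarkers attach
per challenge: only measurements on or before the challenge date and at
most 365 days earlier are eligible (the boundary day is kept), and the
most recent eligible value wins. SPT is saline-subtracted and floored at
0 mm (negative net wheals carry no signal and observed ranges start at 0);
sIgE is capped at 101 kU/L, mimicking clinical lab reporting; the
sIgE/total-IgE ratio is computed *after* capping, since the capped value is
what a lab reports. Records lacking markers are retained — outcome-only
analyses (survival, Cox) use every challenge, and ROC stages drop missing
values per marker — which is why the per-analysis n varies. Every rule
writes one row of a filter log whose counts telescope exactly.

## Dose-to-reaction survival

Per-food cumulative incidence uses the Kaplan-Meier product limit on the
dose axis. Event doses sit on the discrete ladder, so ties are pervasive:
tied events decrement the risk set simultaneously, and challenges censored
at a dose remain at risk for events at that same dose. The median CTD is
the smallest observed event dose at which cumulative incidence reaches 0.5
(undefined when incidence never reaches 0.5, as for foods where fewer than
half of challenges are positive). Equality of curves across strata is the
standard log-rank test (delegated to `lifelines`).

## Frailty Cox model

Challenge outcome is modelled with hazard
`h_ij(d) = h0(d) exp(x_ij'β + b_i)`, `b_i ~ N(0, σ²)` a Gaussian random
intercept per participant (participants contribute a median of several
challenges), with fixed indicator adjustment for challenge food (reference
= most frequent food). One univariable, food-adjusted fit is produced per
clinical/demographic feature.

Estimation maximizes the Breslow-ties penalized partial likelihood over
(β, b) by damped Newton iterations (step-halving enforces a monotone
objective; convergence at gradient norm < 1e-8 relative), and profiles σ²
by maximizing the Laplace-approximate integrated likelihood
`l_p(β̂, b̂) − b̂'b̂/2σ² − (q/2)log σ² − ½ log det(H_bb + I/σ²)` over a
10-point log-spaced grid on [1e-4, 4] refined by golden section. The σ² → 0
limit reproduces the ordinary Cox fit continuously. Breslow rather than
Efron tie handling is a deliberate choice: with doses on a ~9-rung ladder,
tie groups are huge, Breslow keeps the likelihood and its derivatives exact
and cheap (two matrix products per evaluation), and the original software's
default (likely Efron) can differ slightly — a documented divergence.
Wald 95% CIs use the β block of the inverse penalized information. With
heavy tying and moderate cluster sizes, penalized-likelihood estimates of β
are mildly shrunk and σ² is estimated with substantial noise; the recovery
test budgets 3 standard errors for β and a [0.1, 0.5] band for σ² at its
true 0.25.

## Binary (logistic) ROC thresholds

Per food and marker, candidate cutoffs are midpoints between adjacent
distinct observed values plus open endpoints; positivity is marker
*strictly above* the cutoff; Se(c) = P(X > c | positive),
Sp(c) = P(X ≤ c | negative). The Youden-optimal cutoff maximizes
J = Se + Sp − 1, with ties broken toward the smallest cutoff (maximizing
sensitivity). AUC is the tie-corrected Mann-Whitney statistic, identical
to trapezoidal integration of the empirical ROC polygon (asserted in
tests). Joint two-marker models are maximum-likelihood logistic fits
(`statsmodels`), scored by the apparent (in-sample) AUC of the fitted
linear predictor — no cross-validation, matching a single reported AUC per
model; apparent AUC is monotone under added predictors, so joint ≥ single
on the same complete cases. Complete separation is flagged, not fatal: the
separating predictor still gives AUC 1.

## Dose-dependent (CTD) ROC

The cumulative/dynamic time-dependent ROC at dose horizon t (default
500 mg): cases react by t, controls are reaction-free through t.
Challenges censored exactly at t (the 500 mg negatives) count as controls;
this is the convention under which the dose-dependent analysis at 500 mg
coincides exactly with the binary analysis when no censoring occurs before
the horizon — an identity asserted in tests and a useful sanity anchor,
since in this design negatives *are* censored exactly at 500.

Two estimators serve different tasks, mirroring the two-package practice
this analysis style comes from:

* **Threshold selection** uses subset product-limit curves combined by
  Bayes' rule: `Se(c,t) = (1 − S(t|X>c)) P(X>c) / (1 − S(t))`, analogously
  for Sp. Subset-KM sensitivities are not automatically monotone in c (a
  known pathology); violations are clipped to monotone and counted.
* **AUC** uses inverse-probability-of-censoring weighting: events at
  T_i ≤ t weighted by 1/G(T_i−), G the reverse-KM censoring survival;
  the constant control weight 1/G(t) cancels. With no censoring before t
  this is exactly the Mann-Whitney AUC.

PPV(c,t) = 1 − S(t | X > c) and NPV(c,t) = S(t | X ≤ c) from the subset
curves. When a component is inestimable at the requested horizon (e.g. a
food where every challenge is positive, so nobody is at risk beyond the
last event dose), the analysis steps down to the largest estimable event
dose and records it as `effective_horizon_mg`. Threshold-stratified
Kaplan-Meier curves (above vs at-or-below) with a log-rank p complete the
per-food output. The nearest-neighbour smoothed estimator available in
some software is deliberately out of scope: the subset product-limit is
deterministic and oracle-testable.

## Method comparison and concordance

Per (food, marker), 1,000 bootstrap resamples of challenge records
recompute both AUCs; the percentile 95% CI of the paired difference
(dose-dependent − logistic) flags a difference when it excludes 0.
Resampling is at the record level within food by default; a
participant-level option exists because repeat challenges violate
record independence. Thresholds are *not* re-derived per replicate
(they enter only the concordance analysis); replicates where either AUC is
inestimable are redrawn and counted, and a comparison needing more redraws
than replicates is flagged unreliable.

Concordance, among positive challenges with both markers present,
classifies each record against the two dose-dependent thresholds
("above" strictly greater, consistent with ROC positivity); accuracy is
the both-above plus both-below percentage, and the overall agreement pools
records across foods (equal to the record-count-weighted mean of per-food
accuracies).

## Synthetic cohort generator

The generator (`ctdroc.simulate`) is first-class, tested code providing
ground truth for everything downstream. Per participant: demographics and
atopy flags drawn to match the observed cohort's margins (61% male, 62%
asthma, 77% rhinitis, 73% atopic dermatitis, median age ~9), a frailty
`b_i ~ N(0, 0.5²)`, and per-food challenge propensities proportional to
observed per-food challenge totals (427 participants, ~1,250 challenges at
default size). Per challenged (participant, food): an allergic status with
probability equal to the observed per-food positive fraction; log-scale
SPT/sIgE markers from a bivariate Normal (correlation 0.6, case-control
separation 1.5 on the log scale, i.e. binormal AUC ≈ 0.86 — matching
cohorts where most marker AUCs exceed 0.75); and a latent log10 eliciting
dose `D* = α_f − γ z + b_i + ε`, with z the standardized mean of the two
log-markers, γ = 1.2, ε ~ N(0, 0.5²) — an accelerated-failure-time form
chosen over a hazard model because reactions land on discrete escalating
rungs, which reproduces the interval/right-censoring structure naturally.
The reaction occurs at the first rung reaching 10^D*; CTD is the previous
rung. Per-food intercepts α_f are solved numerically (mixture-normal CDF,
Brent) so the expected positive fraction equals the observed per-food
fraction, capped at 0.995 for the all-positive food. Total IgE is the sum
of the participant's sIgE draws plus a lognormal background (median
~400 kU/L). 10% of (participant, food) pairs are re-challenged at a later
date; 5% of biomarker sets are deliberately stale or post-challenge to
exercise the 12-month window rules; FEV1 and FEV1/FVC carry ~40-55%
missingness as in real covariate tables.

What the generator does *not* emulate: adverse-event severity grades,
placebo reactions, the conditioning of pistachio challenges on cashew
positivity (propensities are independent Bernoullis), real covariate
effects on outcome (HRs are null by construction unless injected), or
assay-specific measurement error. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
clinical validity of any particular threshold. A separate
proportional-hazards generator (`simulate_ph_frailty`) provides exact-model
data for frailty-Cox parameter recovery, since the AFT cohort model is not
the Cox model's own data-generating process.

## Numerical conventions and degenerate inputs

* Percentages print as integers rounded half-up (matching conventional
  table formatting; verified against all published rows recomputed from
  their own numerators/denominators).
* `survival_at` returns NaN beyond the last observed dose unless the curve
  has already reached 0 — the signal used by the horizon-fallback rule.
* Youden ties break toward the smallest cutoff; argmax over midpoint
  cutoffs is exhaustively checked against brute force.
* Linear predictors are clipped at ±200 before exponentiation in the Cox
  code; Newton steps are halved until the penalized objective does not
  decrease.
* Empty strata, single-class foods, all-censored inputs, zero total IgE,
  and missing saline controls all take defined paths (error, skip-with-
  reason, or NaN) rather than propagating silently.

## Problem sizes

Default report runs use the full-size synthetic cohort (427 participants,
~1,250 challenges, 1,000 bootstrap replicates). The test suite and the
reproduction script use 180-500 participants, 2,000 challenges for
parameter-recovery checks, and 500 replications for null calibration —
sizes at which Monte-Carlo error is small relative to the tested
tolerances while the whole suite stays fast.

## Known limitations

* Breslow ties (see above) can differ in the third decimal from Efron-based
  software on heavily tied data.
* The Laplace profile for σ² is approximate; for very small cluster counts
  the estimate is noisy, and the lower boundary σ² = 0 is admitted.
* Subset-KM threshold selection inherits the non-monotonicity pathology of
  that estimator (clipped and counted, not removed).
* Apparent AUCs for joint logistic models are optimistic relative to
  cross-validated ones.
* The concordance analysis conditions on positive challenges only; it says
  nothing about agreement among negatives.
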