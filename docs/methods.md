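# Methods

This note documents the models implemented in `claimstte`, the synthetic
data-generating process (DGP) used to verify them, the numerical choices,
and the limitations of both.

## Study design being emulated

The package emulates two pragmatic trials in patients with gout and
peripheral artery disease (PAD) who initiate urate-lowering therapy (ULT)
with gout-flare prophylaxis, in a Medicare-like claims setting:

1. **Initiator trial.** Arms are defined by the prophylaxis drug dispensed
   with ULT initiation (colchicine vs NSAID).  The estimand is the
   intention-to-treat analogue: patients keep their initiation arm
   regardless of later discontinuation.
2. **Duration trial.** Arms are sustained strategies after colchicine
   initiation: *long-term* (colchicine daily indefinitely) vs *short-term*
   (daily through day 90, then stop).  The estimand is per-protocol;
   estimation uses cloning, censoring at protocol deviation, and
   inverse-probability-of-censoring weighting.

Eligibility (both trials): age > 66 years (exclusive) at the index date;
continuous enrollment through a 183-day lookback; gout and PAD diagnoses
on or before index; at least one health-system contact in the lookback;
no advanced kidney disease (stage 4–5/ESKD) or hepatic failure in the
lookback; a 183-day washout of ULT, colchicine and NSAIDs; and exactly one
prophylaxis class dispensed within a pairing window (default 14 days) of
the first ULT dispensing — same-day users of both classes are excluded.
Criterion failures are attributed to the first failing criterion, in the
order enrollment → age → required diagnoses → health-system use →
exclusions → study window, giving a deterministic attrition table.

The primary outcome is the 2-year composite of MACE, major adverse limb
events (MALE) and all-cause death; secondary outcomes are MALE+death,
MACE+death, and each component.  In MACE-only and MALE-only analyses the
competing risk of death is a **non-censoring event**: the dead stay in the
risk set, event-free and with their weight, through the horizon, so the
estimate is a cumulative incidence in the presence of death (a total
effect), not a cause-specific quantity.

## Estimators

**Propensity and weights (trial 1).** A maximum-likelihood logistic model
of the colchicine-arm indicator on main effects of all baseline covariates
(age, sex, race, comorbidities, PAD-severity markers, medication history,
antihypertensive-count indicators, Elixhauser score, calendar time and
enrolment duration in 30-day blocks, gout-encounter history, ULT drug,
prior steroid use).  Stabilized weights `P(arm)/p_i` and `(1−P(arm))/(1−p_i)`
are truncated at the pooled (both arms, upper-tail only) 99th percentile.
Constant columns are dropped with a warning; so is any binary covariate
with an empty covariate-by-arm cell, whose coefficient MLE is infinite —
this keeps bootstrap resamples of small cohorts estimable without
changing the population model.  Remaining non-convergence or separation
is an error naming the offending covariates.

**Balance.** Categorical covariates: absolute difference in (weighted)
proportions.  Continuous covariates: absolute mean difference divided by
the *unweighted* pooled SD `sqrt((s1²+s0²)/2)`, used in both the pre- and
post-weighting columns so they share a denominator.  Differences above
0.10 are flagged.

**Weighted Kaplan–Meier.** A weighted product-limit estimator with
events-before-censorings tie handling; censoring events are disenrollment,
the administrative study close, and the analysis horizon.  Risks are read
off right-continuously at the horizon.

**Clone–censor–weight (trial 2).** All trial-1-eligible patients are
cloned into both strategy arms (NSAID initiators deviate immediately and
contribute to interval-0 censoring models only).  Time is discretized into
30-day intervals `[30k, 30(k+1))` from the index date; a 730-day horizon
is rounded down to 24 whole intervals.  On-treatment state comes from
dispensing `days_supplied` coverage with a configurable grace period
(default 30 days) bridging refill gaps.  Deviation rules: the long-term
clone deviates when the bridged course ends (+grace); the short-term clone
deviates at an early stop before day 90 or at the first coverage start at
or after day 90 + grace (supply prescribed before day 90 may run past it).
Before day 90 both strategies demand identical behaviour, so an early stop
censors both clones.  Events in the deviation interval count when the
event day is on or before the deviation day (ties: event).  Clones frozen
by the competing-risk convention (after death) can no longer deviate.

Censoring weights are stabilized and fit **per arm**, pooled over
intervals: denominator `P(uncensored_k | baseline covariates, current
steroid use, k, k², k³)`, numerator the same with time terms only; the
cumulative product over intervals is truncated at the pooled 99th
percentile across person-intervals.  Per-arm fits were chosen (the
alternative is a joint fit with arm terms) because the deviation
mechanisms differ structurally before and after the day-90 switch.

The outcome model is a weighted pooled logistic regression of
event-in-interval on intercept, arm, k, k², k³ and arm×k (higher-order
arm interactions off by default); standardized risk at interval K is
`1 − Π_{k≤K}(1 − h_k)` with arm fixed.  A saturated-time variant (one
hazard per arm-interval cell, computed in closed form as the weighted
event fraction — the exact MLE of the saturated binomial model) exists
for equivalence checks against the discretized Kaplan–Meier.

**Bootstrap.** Percentile intervals from patient-level resampling with
replacement (cohort size preserved), re-running the entire estimator —
propensity/censoring refits and re-cloning included — in each resample.
Clones of one patient are dependent and are never split across resamples.
One root seed spawns an independent stream per resample.  Failed resamples
are excluded and counted; more than 10% failures aborts.

## Synthetic data-generating process

The generator emulates the *structure* of linked claims: six tables
(patients, enrollment spans, diagnoses, dispensings with prescribed
durations, outcome events, deaths) with integer-day timing.  Day 0 is an
epoch well before the study window (so birth dates are non-negative); the
study window opens at day 40000 and spans ~12.5 years; follow-up is
simulated for at most 5 years.

Defaults are calibrated to the conditions of the emulated study:

* **Covariates** — independent draws matched to the cohort's prevalence
  profile (e.g. 68% male, 54% coronary disease, 44% atrial fibrillation,
  52% diabetes), age ~ N(77, 6.8) truncated above 66, Elixhauser score an
  integer 0–15 (~N(4.9, 2.9)) carried directly on the patients table
  (code-to-score mapping is out of scope), enrolment duration ~N(60, 37)
  blocks.  No claim is made about the real joint distribution; optional
  dependence is deliberately absent.
* **Treatment assignment** — logistic with marginal colchicine share ~54%
  and positive coefficients on atrial fibrillation, heart failure,
  anticoagulation, Elixhauser and (negative) enrolment time, reproducing a
  pre-weighting imbalance pattern with ~5 covariates above the 0.10
  threshold.
* **Dispensings** — one 30-day supply per interval while on treatment;
  geometric discontinuation (per-interval stop probability 0.11 colchicine
  / 0.20 NSAID → mean prescribed durations ≈ 250 and 150 days); current
  steroid use lowers stop odds (flares keep patients on prophylaxis).
* **Flares** — steroid dispensings with base per-interval probability
  0.05, raised by baseline steroid history and (odds ratio e^0.8) by being
  off prophylaxis.  This rebound makes current steroid use a *marker of
  recent discontinuation*, which is why the fitted remaining-uncensored
  coefficient for steroid is negative — the time-varying confounding the
  censoring weights must and do model.
* **Hazards** — per-interval logistic hazards (~0.63% MACE, 0.19% MALE,
  0.56% death at the covariate centre) with comorbidity effects, giving a
  2-year composite risk ≈ 31%.  `strategy_effect` multiplies the hazard
  while exposed to colchicine (default 1.0 = null).
* **Disenrollment** — 0.4% per interval, covariate-independent.

The **counterfactual oracle** reruns the same covariate/flare/hazard
machinery with treatment forced to a strategy (always-colchicine,
always-NSAID, colchicine-indefinite, 90-days-then-stop), no
discontinuation and no censoring, over a large Monte-Carlo sample,
returning true risks with binomial standard errors.

What the generator does **not** emulate: real code vocabularies, correlated
comorbidity structure, provider/geography, claim reimbursement fields,
treatment re-initiation after discontinuation, covariate-dependent
disenrollment, or misclassification.  Passing recovery tests therefore
demonstrates estimator correctness under a known, well-specified DGP —
not robustness to the misspecification real data would bring.

## Verification harnesses (problem sizes)

Monte-Carlo scales were chosen as the package's own verification budget:

* IPT recovery: 200 cohorts of n=2000 under a persistent-treatment DGP
  variant (no discontinuation, hazard multiplier 0.75 on MACE/MALE).  The
  variant exists because with discontinuation the intention-to-treat
  contrast and the always-treated oracle contrast are different estimands.
* Immortal time: 100 replicates of n=5000 under an exact-null variant
  (steroid-independent hazards, so both duration strategies share one
  counterfactual risk); the naive observed-duration grouping must be
  significantly negative and the clone–censor–weight mean within 3
  Monte-Carlo SEs of zero.
* Bootstrap coverage: 100 replicates of n=1000 with B=100; the 95%
  percentile interval must cover the oracle risk difference 90–99 times.
* Oracle checks use 200 000 Monte-Carlo draws.

`scripts/acceptance.py` runs a single n=4000 study end to end with
B=200/B=60 bootstrap resamples for trials 1/2.

## Numerical choices and edge cases

* Half-up decimal rounding for all display values (so `1/0.054 → 19`);
  full-precision values are always retained alongside.
* NNT (negative RD) vs NNH (positive RD) labels; a zero RD or zero
  comparator risk yields an `undefined` flag rather than an exception.
* Weight truncation uses the `higher` order statistic as the cap, making
  truncation idempotent as well as monotone.
* Ties events-before-censorings everywhere, including the discrete
  interval adjudication (event day ≤ deviation day counts the event;
  deviation day equal to a censoring day is a censoring).
* Partial terminal intervals of censored clones are dropped (risk sets are
  defined at interval starts); event-bearing partial intervals are kept.
* Covariates are centred at their configured means inside the DGP's linear
  predictors, so intercepts are interpretable as centre log-odds.
* Degenerate inputs: empty arms, non-positive weights, fitted
  probabilities of 0/1, a horizon not divisible by the interval length
  (in the cloning primitive), and unknown strategy labels all raise typed
  errors; an arm with no deviations degenerates its censoring weights
  to 1 with a log note.

## Limitations

* The pooled censoring model uses cubic time; a deviation process
  concentrated in a single interval (e.g. when no one ever discontinues)
  is quasi-separated in time and correctly raises rather than returning a
  silently bad fit.
* The trial-1 per-protocol variant (censoring at treatment changes) is not
  defined here beyond the ITT analogue; the design question of what
  constitutes a deviation for NSAID initiators is left open deliberately.
* Percentile intervals are first-order; no BCa or studentized correction.
* With 1 observation per patient-interval and moderate n, the arm×k
  interaction is weakly identified early in follow-up where the short and
  long arms share data by construction.
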