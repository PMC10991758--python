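# Methods

`trialemu` studies three methodological biases that distort treatment-effect
estimates in observational hospital cohorts — competing risks, immortal-time
bias, and baseline confounding — on synthetic COVID-19-like inpatient data
with known ground truth. This note documents the data-generating model, the
estimators, the numerical choices, and the limits of what the synthetic
experiments can show.

## The synthetic cohort generator

### Structure

Time is a discrete daily grid: admission is day 0 and terminal events occur
on integer days 1..45 (the administrative follow-up horizon). Each patient
carries baseline covariates

- age ~ Normal(66, 13) years, truncated to [18, 100];
- sex ~ Bernoulli(0.62) (male);
- Charlson comorbidity index ~ Poisson with log-mean depending on age and a
  latent severity factor, capped at 12;
- five inflammatory markers (CRP mg/L, LDH U/L, D-dimer ng/mL, lymphocyte
  count 10^6/L, ferritin mcg/L), log-normal with a shared latent severity
  factor loading on all five (negatively on lymphocytes). Locations and
  dispersions are chosen so the clinical high-risk thresholds (CRP > 102,
  LDH > 394, D-dimer > 1,580, lymphocytes < 760, ferritin > 1,360) sit near
  the outer quintile of each marker;
- pandemic wave ∈ {1, 2, 3} with probabilities (0.45, 0.30, 0.25).

The latent severity factor exists only to induce realistic correlation
among the markers and the comorbidity index; hazards and treatment uptake
depend on the *observable* covariates, so measured-covariate adjustment can
in principle remove all confounding.

### Event and treatment processes

Each in-hospital day, an untreated patient may initiate the single-dose
treatment with probability `expit(a_d + x'c)`, where the intercept takes one
value during the 2-day grace-reference window and a lower value afterwards.
Two intercepts are required because the cohort margins pin down both the
fraction treated within 2 days (15.3%) and the fraction ever treated
(29.9%); no constant daily hazard satisfies both.

Terminal events are drawn by first sampling "any event today" with
probability `1 − exp(−Σ_k h_k)` from the three cause-specific daily rates
`h_k = exp(b_k + x'β_k + treated·θ_k)` (death, discharge home, transfer),
then assigning the cause multinomially with probabilities proportional to
`h_k`. This two-stage draw guarantees at most one terminal event per
patient and avoids same-day cause ties. Patients event-free at day 45 are
administratively censored.

**Treatment-effect timing.** Treatment initiated on day *t* multiplies the
cause-specific rates from day *t+1* onward. A same-day event can therefore
never be caused or prevented by same-day initiation, and the counting-process
representation never contains zero-length treated intervals. The default
true effects are hazard ratios 0.70 (death), 1.15 (home), 1.10 (transfer).

### Calibration

The intercepts (three baseline log-rates, two initiation logits) were fixed
by damped stochastic-approximation iterations against large simulated
cohorts until six marginal frequencies matched the reference hospital
cohort: 38.3% in-hospital death, 49.6% discharge with 58.6% of discharges
home, 12.3% administrative censoring, 29.9% ever treated, 15.3% treated
within 2 days. A 500,000-patient verification run at a held-out seed
reproduces all six within 0.3 percentage points. Covariate coefficients
(confounding by indication: older, more inflamed, lymphopenic patients are
both likelier to be treated and likelier to die) are design choices on the
per-SD scale, not calibrated quantities.

### Missingness

Only the five inflammatory markers can be missing. MCAR blanks values
uniformly; MAR makes missingness depend on age and pandemic wave (both
fully observed), with the per-marker intercept solved by bisection so the
realized marginal rate matches the configured rate in expectation on the
cohort at hand.

## Estimators

### Nonparametric curves

Weighted Kaplan-Meier and Aalen-Johansen estimators accept late-entry
(start, stop] rows so that time-varying inverse-probability weights enter
both the event counts and the risk sets. Risk sets are `{i: start < t ≤
stop}`: at a tied day, events precede censorings. The naive
one-minus-Kaplan-Meier "cumulative incidence", which treats competing
events as censoring, is provided deliberately: it dominates the
Aalen-Johansen CIF everywhere and is the biased comparator in the
competing-risks demonstration.

### Cox engine

A single Newton-Raphson partial-likelihood maximizer serves every
regression in the package: start-stop risk sets, case weights, Efron
(default) or Breslow ties, and a cluster-robust sandwich variance built
from score residuals grouped by source patient (clones and intervals of one
patient share a group). Efron is the default because daily grids produce
heavy ties. Numerical choices: covariates standardized internally
(coefficients reported on the original scale), convergence when the
relative change in log partial likelihood falls below 1e-9 (max 50
iterations) with step-halving on likelihood decreases, coefficients capped
at ±20 on the standardized scale, and a monotone-likelihood flag raised
beyond ±10 (fitted probabilities saturate; the reported estimate is a
boundary artifact, and a warning is emitted). Coefficients, model-based and
robust standard errors were verified against `survival::coxph` (values
frozen into the test suite) and brute-force likelihood grids.

### Fine-Gray subdistribution analysis

The expansion keeps competing-event patients in the target-cause risk set
until the end of follow-up with time-varying weight G(t−)/G(T−), where G is
the Kaplan-Meier estimate of the censoring distribution of the requested
cause partition (administrative censoring only in the 3-event analysis;
administrative plus transfer in the 2-event analysis). Censoring times are
shifted half a day in the estimation of G so that, at tied days, censorings
act after events; under this convention the unadjusted subdistribution
product-limit estimator reproduces the Aalen-Johansen CIF to machine
precision, which the tests verify on random datasets. Weights are floored
at 1e-8. Subdistribution hazard ratios come from the weighted Cox engine
with patient-clustered robust variance.

### Weighting

The propensity model for IPTW (Model 4) is a logistic regression of *ever
treated* on the transformed baseline covariates — log CRP, LDH, D-dimer and
ferritin, square-root lymphocytes, age, sex, CCI, wave indicators. Weights
are stabilized by default (mean ≈ 1), truncated at the 99th percentile, and
propensities floored at 1e-6. The weighted time-dependent Cox model uses
robust standard errors.

The censoring model for the emulation is a discrete-time daily logistic
model of being artificially censored, fitted separately per day within each
arm (the saturated-in-time version of a pooled daily model, natural for a
2-day window in which one arm can only be censored on the final day; days
with no censoring contribute probability one, and a degenerate fit falls
back to the marginal daily rate). Clones whose terminal event falls on day
*s* are excluded from the day-*s* censoring risk set: events precede the
end-of-day censoring decision, so those clones were never censorable.
Weight timing follows the same logic: the day-*s* censoring factor enters
the weights from day *s+1* onward (weight 1 on (0, 1]), because the
selection it corrects has by then acted on the risk set. Under randomized
initiation, re-weighting reconstructs the cohort size in each arm
(pseudo-population identity, tested); under confounded initiation the
identity holds only as well as the censoring model is specified.

### Clone-censor-weight emulation

Every patient is cloned into a "treated within the grace window" arm and a
"not treated within the grace window" arm. A treated-arm clone of a patient
not treated by the end of the grace window is artificially censored at the
grace end; a control-arm clone of a patient initiating on day t ≤ grace is
censored at t; clones whose event falls on or before their deviation day
keep the event in both arms. Initiation *after* the grace window does not
censor the control clone (the strategy constrains the grace window only); a
strict never-treat control strategy is available via the protocol. "Within
2 days" means treatment_day ≤ 2 with admission as day 0.

Per-arm weighted Aalen-Johansen curves and per-cause weighted Cox fits (arm
indicator as the sole covariate, patient-clustered robust variance)
summarize the emulated trial. Confidence intervals use a patient-level
nonparametric bootstrap (patients, not clones, are resampled; default 500
replicates; replicate-indexed seed substreams make results reproducible),
normal-based on the log-HR scale and exponentiated, or on the probability
scale for CIF differences. A replicate failure rate above 10% aborts with a
diagnostic.

**Estimand caution.** Because treatment acts from the day after initiation,
the two strategies share identical hazards during any part of the grace
window before treatment can bite, which dilutes the emulated hazard-ratio
contrast toward the null relative to the instantaneous cause-specific HR.
The parameter-recovery experiments therefore randomize initiation on day 1
with a 1-day grace window, reducing the dilution to the single unavoidable
lag day (residual attenuation ≈ +0.03 on the log-HR at the default event
rates, measured by simulation). With longer grace windows the emulated
per-protocol effect is a genuinely different — smaller — estimand than the
per-day hazard ratio, which is worth remembering when comparing Model 5
against Models 2-4 on the same cohort.

### Multiple imputation

Chained equations on the analysis scales with proper Bayesian
linear-regression draws (variance from the scaled inverse-chi-square
posterior, coefficients from their normal posterior, residual noise added),
m = 5 copies, 10 cycles, initialized from random observed draws.
Predictors: all other baseline covariates, the other markers' current
imputations, event-type indicators, and the all-cause Nelson-Aalen
cumulative hazard at the event day — including the outcome information that
survival-model congeniality requires. Pooling uses Rubin's rules with
Barnard-Rubin degrees of freedom; log hazard ratios are pooled on the log
scale. With zero missingness the imputer returns identical copies, so the
wrapped pipeline is bitwise equal to the complete-data pipeline.

## The five-model comparison

| Model | Analysis | Immortal time | Confounding |
|---|---|---|---|
| 1 | Univariable Cox, ever-treated misclassified as treated from admission | ignored | ignored |
| 2 | Univariable time-dependent Cox, start-stop treatment | addressed | ignored |
| 3 | Multivariable time-dependent Cox with baseline covariates | addressed | addressed |
| 4 | IPTW-weighted time-dependent Cox, robust SE | addressed | addressed |
| 5 | Clone-censor-weight emulation, bootstrap CI | addressed | addressed |

Each model is fitted per cause-specific endpoint (death, discharge home,
transfer; competing causes censored at their event day). When markers are
missing, every model runs on each imputed copy and the log-HRs are pooled;
Model 5 uses its bootstrap variance as the within-imputation variance.

## Experiment sizes

The routine checks use the sizes at which their Monte-Carlo error makes the
assertion meaningful rather than the largest sizes the hardware could
sustain: calibration margins at n = 50,000 (binomial SE ≈ 0.2pp against a
±1.5pp band); immortal-time direction at n = 5,000 × 50 replicates;
parameter recovery at n = 2,000 × 200 replicates with 100-replicate
bootstrap CIs per replicate; balance and MI contracts at n = 5,000.

## What the synthetic experiments do and do not show

The generator reproduces the reference cohort's margins and a plausible
confounding-by-indication structure, but it simplifies in ways real
registry data do not: covariates are time-fixed (no post-baseline
confounding, which the emulation therefore cannot be stress-tested
against), hazards are day-constant apart from covariate and treatment
effects, the latent-factor correlation structure is stylized, and
missingness mechanisms are exactly MCAR/MAR. Passing tests demonstrate that
the estimators do what their theory promises under their assumptions — not
that those assumptions hold in any particular hospital registry. Known
limitations: no variance estimators for the nonparametric curves, no
stratified or time-varying-coefficient Cox, covariate-independent censoring
distribution in the Fine-Gray expansion, and hazard-ratio summaries only
(no risk differences or ratios).
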