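# Methods

This note records the modelling assumptions, default parameters and
numerical choices behind the simulation framework, and what the shipped
test conditions do and do not demonstrate.

## Cohort generator

Baseline covariates are drawn mutually independently: age uniform on
[40, 69] years; female with prevalence 0.59 (the published composition of
the motivating cohort, 24,469 women of 41,514 participants); education
(0.30 / 0.45 / 0.25), country of birth (0.70 AUS-NZ / 0.10 UK / 0.20
Mediterranean), smoking (0.55 never / 0.30 former / 0.15 current),
physical activity (uniform over four levels) and alcohol (0.30 / 0.40 /
0.20 / 0.10). Only the female prevalence is anchored to a published
number; the remaining marginals are round, plausible values for an
Australian cohort of this era and are deliberately *not* claims about any
real dataset — what matters downstream is how the exposure, event and
missingness models depend on the covariates, not the marginals
themselves. All prevalences are overridable via the `cohort:` config
section. The gap between waves is fixed at 13 years for every subject;
individual attendance dates are out of scope.

## Exposure model

(WC₁, WC₂) given the covariates is bivariate normal with a linear mean in
the fixed design (age, sex and k−1 indicators per categorical) and a
shared 2×2 residual covariance. The default coefficients were chosen so
the implied marginal covariate–WC₁ correlations have the observed signs
and rough sizes (age +0.18, female −0.52, tertiary education −0.18,
Mediterranean origin +0.19, smoking +0.17, physical activity −0.13,
alcohol +0.05); both waves share the coefficients, wave 2 adding a +2 cm
secular intercept shift.

Calibration is closed-form rather than iterative: with V = β′Σ_X β the
covariate-explained variance (Σ_X computed analytically from the
configured marginals), the residual variance is 13² − V per wave and the
residual covariance 0.81·13² − V, so the generating model has marginal
SD 13 cm and marginal corr(WC₁, WC₂) = 0.81 *exactly*; the sample
correlation then fluctuates binomially around 0.81 (observed 0.808 at
n = 41,476). The residual (partial) correlation implied by the defaults is
≈ 0.71.

An interpretation was required over whether the lifestyle covariates enter
the exposure mean model or only its covariance: they enter the mean model,
which suffices to reproduce every printed constraint.

## Event generation

Cancer and death times are conditionally independent Weibull
proportional-hazards draws on the *years-from-wave-2* clock,
S(t│lp) = exp(−scale · t^shape · e^lp), inverted as
t = (−log u / (scale·e^lp))^(1/shape). The cancer predictor is
α₁(WC₂−WC₁) + α₂WC₁ + α₃Female + α₄Age + education + country terms with
α₁ = log(true HR)/10 per cm; death uses sex and age only (no separate
intercept — it is absorbed into the Weibull scale). Nuisance values
(shape 1.2 / scale 2.7e-4 for cancer; shape 1 / scale 1.5e-4 for death;
α₂ = 0.01/cm, α₄ = 0.03/y, δ_age = 0.09/y, δ_female = −0.3) were set once
to give mild positive age and WC₁ effects and, over the 6.1-year
administrative window, ≈ 2.7% cancer incidence and ≈ 12% deaths at the
default cohort — plausible for colorectal cancer in this age range. The
**high-incidence profile** multiplies the cancer scale tenfold (≈ 23%
incidence) so that reduced-size runs retain enough events for stable Cox
fits; it is the profile used by the desk-scale checks. Follow-up is then
expressed on the age clock: entry at age + 13, exit at entry plus the
resolved follow-up time.

Generating on the study clock with baseline age in the linear predictor,
while *analysing* on the age clock, leaves a residual misspecification:
within an age-a risk set, time-since-entry (through t^{shape−1}) and entry
age vary and are not captured by the analysis model. Because the change
score is independent of all covariates by construction, these terms act as
independent frailty and attenuate the fitted log(HR) slightly even on
complete data — measured at ≈ −0.005 on the event-rich desk profile
(paired replicates), and proportionally smaller at realistic incidence.
This attenuation affects complete-case and MI identically and is inherent
to the design being studied, not to either missing-data method.

## Missingness

MCAR removes an exact count, round(p·n), chosen uniformly. The
covariate-dependent MAR scenarios use the fixed odds-ratio table (WC₁ per
10 cm, age per year, and 13 categorical indicators); the enhanced scenario
doubles every log-OR. The intercept is calibrated by monotone bisection on
[−50, 50] until the *expected* proportion — the mean predicted probability
over the cohort — is within 1e-6 (1e-4 in the quick checks) of target;
missingness is then drawn as independent Bernoulli trials, so realised
proportions vary binomially. The exact-count/expected-proportion split
mirrors the two mechanisms' definitions: a "random sample" versus a
probability model calibrated "approximately". Missingness never touches
any column except WC₂.

## Imputation model

A proper Bayesian normal linear regression of WC₂ on: intercept, WC₁, the
full covariate design, the cancer-vs-censored event indicator, and the
Nelson–Aalen cumulative hazard **accumulated over the subject's at-risk
interval**, H(exit age) − H(entry age), computed with
left-truncation-aware risk sets on the full cohort (the outcome is
completely observed). The at-risk increment rather than H(exit) alone is
used because, under delayed entry, the survival-likelihood factor for a
subject is exp(−[H(exit)−H(entry)]·e^lp): hazard accumulated before entry
was never experienced and carries no information about the subject's
exposure. Empirically this choice reduces the MI attenuation of the
change-analysis estimate by ≈ 0.003 log-HR units on the desk profile.

Each imputation draws σ*² = RSS/χ²(n_obs−k), then
β* ~ N(β̂, σ*²(X′X)⁻¹), then adds N(0, σ*²) residual noise — the standard
proper draw under the flat prior p(β, log σ) ∝ 1. The m imputations use
independent child streams of the replicate seed. Analyses are fitted per
completed dataset and pooled by Rubin's rules; the 95% interval uses the
t distribution with the small-sample df, degenerating to the normal when
the between-imputation variance is zero.

WC₂ is imputed, not the change score, mirroring what an analyst with a
complete wave-1 measurement would do; the change is recomputed after
imputation. This *semi-compatibility* between imputation and analysis
models produces a small negative bias in the change analysis — measured at
≈ −0.006 (MI minus complete-case, paired) on the event-rich desk profile,
and expected to shrink roughly with the event fraction at realistic
incidence. It is a genuine property of the procedure under study, visible
here because the desk profile deliberately inflates the event rate.

## Analysis models

Both Cox models use age as the time metric with delayed entry (risk set at
age a: entry < a ≤ exit), Breslow tie handling (inert for continuous
simulated ages, fixed for reproducibility), and Wald 95% intervals; the
exposure coefficients are per 10 cm. The fitting core is an in-house
Newton–Raphson maximiser of the left-truncated Breslow partial likelihood
using sorted suffix-sum risk-set accumulation (O(n log n) per iteration);
it is validated against lifelines and statsmodels PHReg to ~1e-6 and
against a closed-form two-event example. Degenerate inputs (fewer than two
events, constant covariates, singular information) raise typed errors.

## Experiment orchestration and seeding

Replicate r of a cell derives all randomness from
SeedSequence([master_seed, tag, r]) — tag 0 for cell replicates, 1 for the
complete-data reference — so any replicate is reproducible in isolation
and streams never overlap. A replicate that fails is dropped and logged; a
cell aborts if more than 1% fail, because silently dropping more would
bias the metrics. Truth conventions: analysis (a) is compared with
log(true HR); analysis (b) fits a model different from the generating one,
so its truth is the mean complete-data model-(b) estimate over independent
un-amputed replicates (500 by default; 10,000 in the full profile), and
the "complete SE" is the mean complete-data standard error.

## Problem sizes

The desk profile (n = 5,000, nsim = 200, m = 5, high-incidence events,
HR 1.5, 50% enhanced covariate-dependent MAR) is the package's
acceptance-scale condition: Monte Carlo error on bias ≈ 0.004 log-HR
units, total runtime about a minute. The full profile (n = 41,476,
nsim = 1,000, m = 20, default incidence, 10,000 reference replicates)
reproduces the complete study conditions in roughly an hour per cell on
one CPU; the claims that the log(HR) is estimated to within 1.5% of truth
(HR 1.1) and that Monte Carlo error stays below 0.4% (HR 1.5) refer to
this full scale only and are not checked by the desk-scale suite.

## What the synthetic data do not show

The generator reproduces the *dependence structure* the study design
needs — exposure–covariate associations, the 0.81 wave correlation,
proportional-hazards outcomes, covariate-driven missingness — not any real
cohort's joint distribution: covariates are independent, waist
circumference is exactly conditionally normal, the two waves share
coefficients, and everyone shares one attendance date and one
administrative window. Conclusions about the *comparison of missing-data
methods* transfer to the extent that those stylised features, not the
omitted ones, drive the methods' behaviour; mechanisms where missingness
depends on the outcome or on the missing values themselves (MNAR) are out
of scope.
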