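# waistmi

A simulation framework for studying how missing data in a **repeatedly
measured exposure** affect survival analyses, comparing **complete-case
analysis** with **multiple imputation (MI)**.

## The scientific problem

Longitudinal cohorts re-measure exposures at follow-up waves, and many
participants miss the later waves. When the research question concerns the
*change* in an exposure — here, change in waist circumference between two
waves 13 years apart, in relation to the incidence of colorectal cancer —
every subject with a missing wave-2 measurement either has to be dropped
(complete-case analysis) or have the measurement imputed. This package
implements, end to end, a factorial simulation experiment that quantifies
the bias, precision and confidence-interval coverage of both strategies
when 15–50% of the wave-2 measurements are missing completely at random
(MCAR) or dependent on observed covariates (covariate-dependent MAR).

## The models

**Data generation.** A cohort of n adults aged 40–69 carries demographic
and lifestyle covariates (sex, education, country of birth, smoking,
physical activity, alcohol). Waist circumference at the two waves,
(WC₁, WC₂), is bivariate normal given the covariates, calibrated so that
marginally corr(WC₁, WC₂) = 0.81 with mean ≈ 85 cm and SD ≈ 13 cm. Time to
colorectal cancer and time to death are independent Weibull
proportional-hazards draws, S(t│x) = exp(−λ tᵏ e^{β′x}), with the cancer
linear predictor containing α₁(WC₂−WC₁) where α₁ = log(HR)/10 for a
configured true hazard ratio (1.1 or 1.5 per 10 cm change); follow-up is
censored at death or after an administrative window of 6.1 years.

**Missingness.** MCAR deletes an exact-count random subset of WC₂.
Covariate-dependent MAR draws missingness from a logistic model,

logit Pr(missing) = γ₀ + γ₁·WC₁/10 + γ₂·Age + γ₃·Female + … + γ₁₅·Physical_high,

with fixed odds ratios (e.g. 1.10 per 10 cm of WC₁, 1.80 for current
smoking); an *enhanced* scenario squares every OR. The intercept γ₀ is
calibrated by bisection so the expected missingness hits 15, 30 or 50%.

**Analysis.** Two Cox models on the **age time scale with delayed entry**
at the wave-2 age: (a) the hazard on (WC₂−WC₁)/10 adjusted for WC₁/10,
sex, country of birth and education; (b) the hazard on WC₂/10 with the
same adjustment but *without* WC₁ — making WC₁ a strong auxiliary variable
(ρ = 0.81) available only to the imputation model.

**Multiple imputation.** Missing WC₂ values are drawn m times from a
proper Bayesian normal linear regression on WC₁, all covariates, the
event indicator and the Nelson–Aalen cumulative hazard over each subject's
at-risk interval; estimates are pooled by Rubin's rules,
T = W + (1 + 1/m)·B with df = (m−1)(1 + W/((1+1/m)B))².

Performance per cell of the 2 HR × 3 proportion × 3 mechanism grid: bias
of the log(HR) (analysis (a) against log HR; analysis (b) against a
complete-data reference), empirical SE, and 95%-interval coverage, with
Monte Carlo errors.

## Worked example

The numbered drivers under `analysis/` run the study stages and write
delimited-text tables under `results/`. The headline scaled-down cell
(n = 5,000, 200 replicates, m = 5, event-rich profile, true HR 1.5, 50%
missing under enhanced covariate-dependent MAR):

```sh
python analysis/03_run_desk_cell.py --seed 0
```

prints (about one minute on one CPU):

```
cell: n=5000 nsim=200 m=5 HR=1.5 prop=0.5 mechanism=CDMAR_ENH
analysis        method      bias   emp_se  coverage  mc_se_mean
       a complete_case -0.000032 0.063972      95.0    0.004523
       a            MI -0.007434 0.068374      92.0    0.004835
       b complete_case  0.011908 0.042818      92.0    0.003028
       b            MI  0.006169 0.037889      91.5    0.002679
```

Reading: even with half the wave-2 measurements missing under a strong
covariate-dependent mechanism, both methods are nearly unbiased (bias a
few thousandths of a log-HR against truths of 0.405 and ≈ 0.18) and the
95% intervals cover close to nominally; for analysis (b) — where WC₁ acts
as a strong auxiliary — MI is visibly more precise than complete-case
(empirical SE 0.038 vs 0.043). `mc_se_mean` is the Monte Carlo error of
the bias estimate.

The other drivers: `01_simulate_cohort.py` (generator calibration —
corr(WC₁, WC₂) = 0.808 at n = 41,476, cancer incidence 2.7% on the default
profile), `02_calibrate_missingness.py` (intercept calibration and
realised missingness for every scenario × proportion),
`04_run_grid.py` (the factorial grid at reduced scale, plus the bias /
empirical-SE / coverage figures).

## Layout

```
src/waistmi/        cohort, exposure, events, amputation, coxph (fitting
                    core + Nelson–Aalen), models, mi, experiment, config
analysis/           numbered narrative drivers (simulate → calibrate →
                    desk cell → grid)
tests/              pytest suite, including end-to-end acceptance checks
configs/            structured-text scenario profiles (desk, full)
docs/methods.md     modelling assumptions, calibration and numerics
```
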