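# Methods

## Data model

The analysis dataset is a steady-state trough representation: one row
per monitored occasion carrying the postoperative day (POD), the total
daily dose (mg/day), the whole-blood trough (ng/ml) and that day's
covariates. Troughs are only meaningful after at least three repeated
doses at a constant rate, so no dosing-event records are kept; both
structural models need only (dose, trough, covariates) per occasion.
Laboratory covariates missing on a later occasion are carried forward
within the subject; a covariate missing at the first occasion is a
format error. Troughs below the assay quantification limit (default
2.0 ng/ml) are flagged by the validator and excluded by default, with a
configuration switch to retain them, since real cohorts report troughs
below the calibration floor.

## Structural models

**Michaelis–Menten dose–trough model.** The dependent variable is the
daily dose: `DD = Vm·C0/(f·Km_i + C0)`. This choice follows from the
units of the published residual components (an additive term in mg/day
can only live on the dose side). `Km_i` is the typical `Km` times
covariate factors times `exp(eta_i)`. Covariate forms: power and
exponential terms normalized to the cohort median, a linear additive
term, a `1 + theta·x` scale term for flags and allele counts, and a
saturable Emax term in the daily dose. The early-postoperative time
factor `f = 10/min(POD, 10)` multiplies the covariate-adjusted `Km`
(not just the typical value); with the factor on, predicted day-7 doses
for the stratified scenarios land inside the published recommendation
ranges, which is the behavior the factor exists to produce.

**Theory-based one-compartment model.** Whole-blood troughs are
predicted by composing (i) the steady-state plasma trough of a
one-compartment model with first-order absorption — closed form for
repeated dosing, daily dose split into equal 12-hourly doses, trough at
12 h after a dose, `Ka` fixed at 4.48 h⁻¹ because no absorption-phase
data exist — with (ii) saturable erythrocyte binding
`Cwb = Cp + Cp·HCT·Bmax/(Cp + KD)` (Bmax 418 µg/L, KD 3.8 µg/L).
Hematocrit enters the partition as a volume fraction (percent/100): with
percent the blood:plasma ratio would be ~3500 instead of the
physiological ~35. A configuration switch preserves the literal-percent
reading. The blood→plasma inverse is the positive root of the binding
quadratic, evaluated in the numerically stable form; the round trip is
exact to 1e−9 over the clinical range. The flip-flop boundary
`Ka = CL/V` uses the analytic limit of the trough formula.

Shipped presets `mm_base`, `mm_final`, `theory_base`, `theory_final`
carry the published estimates and serve as simulation ground truth.
Variabilities are exponential with diagonal covariance and reported as
CV% = 100·ω; residual models are additive, proportional or combined.

## Estimation

All objectives share one machinery: per subject, the conditional modes
of the random effects minimize
`q(η) = Σ_j [log v_j(η) + (y_j − f_j(η))²/v_j(η)] + ηᵀΩ⁻¹η`
with the residual variance evaluated at the conditional prediction
(the "interaction" convention). The mode search is a damped Newton
iteration vectorized across subjects (finite-difference derivatives,
coarse joint grid scan on cold starts, gradient-step fallback when the
Newton direction fails). Three marginal-likelihood approximations are
then available:

* `foce` — first-order conditional with interaction: linearize `f` in η
  at the mode, `V_i = G Ω Gᵀ + diag(v(f(η̂)))`, Gaussian −2 log
  likelihood with mean `f(η̂) − Gη̂`.
* `laplace` — exact joint at the mode plus the log-determinant of its
  curvature.
* `agq` — adaptive Gauss–Hermite: nodes centered at the mode and scaled
  by the curvature (default 7 per dimension, configurable).

All three are exact on η-linear Gaussian models (unit-tested against
the closed form at 1e−6) and degenerate to pooled extended least
squares as Ω → 0. Against brute-force quadrature on nonlinear fixtures
at 75% inter-subject variability, the linearized forms deviate by
0.5–0.9% and the 7-node AGQ by ~0.03%; simulation–reestimation showed
the linearized forms additionally bias the combined-error variance
split and can produce a spurious `V → ∞` optimum for the weakly
identified theory-base model, so all inference-grade fits use `agq`.

Fixed effects and variance components are optimized on unconstrained
transforms (log for positive parameters, `log(1+θ)` for scale
coefficients) with L-BFGS-B; convergence at relative OFV change below
1e−11. Standard errors come from the central finite-difference Hessian
of the OFV (covariance `2H⁻¹`, delta method back to natural scale).
Shrinkage: η-shrinkage `100·(1 − SD(η̂)/ω)`, ε-shrinkage
`100·(1 − SD(IWRES))`.

**Stepwise covariate selection** adds, one at a time, the candidate
with the largest OFV drop ≥ 3.84 (χ², p < 0.05, 1 df), requiring at
least a 20% change of the target parameter across the observed
covariate range; backward elimination removes any covariate whose
deletion raises the OFV by less than 6.63 (p < 0.01). Ties break by
declaration order. Operating characteristics are verified on planted
effects sized by a power calculation: a covariate explaining a fraction
R² of the parameter variance yields an expected OFV drop near
`n·log(1/(1−R²))`, which must clear the backward threshold with margin —
the shipped check uses a hematocrit effect explaining ~25% of the `Km`
spread at 150 subjects (expected drop ≈ 40).

## Synthetic cohort generator

The generator emulates an early-post-transplant TDM service. Subject
covariates are drawn from truncated normal (demographics) or truncated
log-normal (right-skewed labs: AST, ALT, bilirubin) distributions whose
parent parameters are solved so the *truncated* mean and SD match the
cohort summary; creatinine clearance is computed by Cockcroft–Gault
from the sampled age, weight and creatinine (×0.85 for women), never
sampled directly. Genotypes are drawn per locus from the reported
genotype frequencies independently for recipients and donor livers,
with a Hardy–Weinberg chi-squared report. Visit counts are
`max(2, 1 + Poisson(4))` (median 5) starting on day 3–6 with 2–4 day
gaps; labs follow slow exponential recovery anchored at the cohort
median day with log-normal noise; steroid doses follow the tapering
protocol.

Dosing starts at 1–2 mg/day and is titrated by
`dose × (target midpoint / measured trough)`, rounded to the 0.25 mg
grid, capped at ±50% change per step, frozen while the trough sits in
the 8–12 ng/ml window, and (for the MM truth) kept below 0.92·Vm. The
clinician reacts to an assay-noised measurement (CV 10%), never to the
noise-free model value. The proportional rule overshoots once near
saturation (the dose→trough map is superlinear there) and settles on
the following correction; an optional absolute step cap is available
but off by default because many small corrections make the dose path
track the random effect and degrade downstream recovery experiments.

Observation noise is realized exactly as the estimation model states
it. Under the MM truth the stored trough is the model-consistent steady
state for the administered dose given the subject's η, and the residual
lands on the recorded daily dose (`DD_row = DD_admin(1+ε₁)+ε₂`);
realizing the residual through the inverse map instead would make it a
function of the stored regressor and bias recovery by construction.
Rows whose simulated dose would fall below 0.05 mg/day are redrawn
(≪1% after two unrecorded early titration steps move first recorded
doses away from the truncation region). Under the theory truth the
stored trough is the prediction times a proportional residual and the
titration feedback uses the recorded noisy value, which makes that
course a statistically valid adaptive design. Model-based simulation
used by VPC/NPDE/bootstrap applies no truncation, so diagnostics on
self-simulated data are exactly calibrated.

What the generator does not reproduce: joint covariate correlations
beyond the Cockcroft–Gault dependence, hepatitis status, antifungal
start/stop dynamics (the flag is constant per subject), and
inter-occasion variability in the PK parameters. Passing recovery tests
therefore demonstrate estimator correctness under the stated design,
not robustness to real-world misspecification.

## Diagnostics

Prediction errors: `PE% = (PRED − OBS)/OBS·100`; MDPE/MAPE are medians
of signed/absolute errors; F20/F30 count |PE| ≤ 20/30% (boundary
inclusive), with I-variants from individual predictions. The bootstrap
resamples subjects with replacement to the original count, refits, and
reports medians, 2.5–97.5 percentiles and bias%; non-converged
replicates are counted but excluded, with a warning status below 50%
convergence. The pvcVPC bins on POD (equal-count, default 8, bins under
5 observations merged left), prediction-corrects each value by the
bin-median typical prediction over its own, and variability-corrects
centered values by the ratio of the across-bin median simulated spread
to the bin's simulated spread; plotting is a thin layer over the
numeric summary. NPDE decorrelates each subject's simulations and
observations with the Cholesky factor of the simulated covariance
(ridge-regularized if singular, and counted), maps continuity-corrected
ranks through the normal quantile function, and combines a t-test
(mean), a chi-squared test (variance) and Shapiro–Wilk (normality) with
a Bonferroni factor of 3 for the global adjusted p-value.

## Dose individualization

For each stratum (CYP3A5 expresser status × antifungal co-therapy ×
hematocrit band × bilirubin band, 48 cells) the engine simulates
subjects with covariates uniform within the band and `Km` variability
from the model, computes each subject's smallest 0.25 mg grid dose
whose day-7 steady-state trough (time factor 10/7) enters the 8–12
ng/ml window, and reports the 2.5–97.5 percentile range rounded outward
to the grid, the median, and the feasible fraction. All strata share
one set of random draws (common random numbers), so cell-to-cell
differences are driven by the covariate effects alone and the clinical
orderings — dose decreasing in bilirubin, hematocrit and antifungal
co-therapy, increasing for CYP3A5 expressers — hold deterministically.
The published table's range-summary rule is unstated, so cell-by-cell
equality is not claimed; the reported check is ordering plus overlap of
the genotype × antifungal spans.

## Experiment sizes and known limitations

Recovery experiments use 500 subjects × ~5 troughs and summarize 3–5
replicate simulate/refit rounds by the median, which is robust to the
occasional fit landing on the wrong branch of a ridge. Two limitations
are documented rather than patched:

* **MM feedback endogeneity.** Under TDM feedback the MM model is an
  inverse regression whose regressor is a parameter-dependent
  deterministic function of dose and η. The marginal likelihood drops
  that design factor, which biases `Km` downward by roughly 15% when
  the unexplained variability is as large as the covariate-free base
  model's (75% CV); the final model, whose covariates absorb much of
  that spread, recovers `Km` within a few percent. Exogenous-design
  refits recover all parameters within ~5%, isolating the cause in the
  design, not the estimator.
* **Theory-base identifiability.** With every trough at the same time
  after dose and no within-subject covariate on disposition, `CL` and
  `V` are separated only by distributional shape. The likelihood is a
  flat curved ridge: replicate MLEs of `V` span a four-fold range even
  under exact-likelihood fitting, and quadrature accuracy shifts where
  along the ridge a given fit lands (these refits use 11 nodes per
  dimension). Median clearance recovers well; the volume estimate from
  this design should be treated as order-of-magnitude only. The final
  model's postoperative-day effect on `V` restores within-subject
  information and with it accurate volume recovery.
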