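# Methods

## The model

`climmed` implements a parallel multiple-mediation analysis of a
province-level climate exposure on binary nutritional-status outcomes.
The exposure X is the annual mean 2 m air temperature (°C) of the
province of residence; the mediators are fruit/vegetable adequacy
(M1, ≥ 5 servings/day, binary) and IPAQ physical-activity level
(M2, low/moderate/high); the outcome Y is overweight (BMI ≥ 25) or,
in a secondary analysis, obesity (BMI ≥ 30). Because M2 is
three-valued, it contributes two parallel pathways — moderate (M21)
and high (M22) activity — contrasted against the low level.

The system consists of three regression equations, estimated by maximum
likelihood equation by equation:

* M1: logit P(M1 = 1) = α₁ + a₁X (+ covariates)
* M2: baseline-category logit vs low,
  log P(moderate)/P(low) = α₂₁ + a₂₁X, log P(high)/P(low) = α₂₂ + a₂₂X
  (+ covariates)
* Y: logit P(Y = 1) = α_y + cX + b₁M1 + b₂₁[M2 = moderate]
  + b₂₂[M2 = high] + covariates + u_j, with a province random intercept
  u_j ~ N(0, σ²)

Covariates are sex (reference male), age in years (linear, uncentered)
and education in four levels (reference university/tertiary).
Sequential estimation is exact here, not an approximation: the three
equations share no parameters and the latent provincial intercept
enters only the outcome equation, so the joint likelihood of the
generalized structural equation model factorizes into the three
equation likelihoods.

Effect decomposition is on the log-odds coefficient scale:

* direct effect: c
* specific indirect effects: a₁b₁, a₂₁b₂₁, a₂₂b₂₂
  (product of coefficients)
* per-path total effects: c + a·b
* raw difference between two indirect effects, e.g. a₁b₁ − a₂₂b₂₂,
  used to compare mediator importance.

No rescaling to probabilities or odds ratios is applied; products of
log-odds coefficients are a scale-dependent summary and are reported
as such (a documented limitation shared with the coefficient-product
tradition of mediation analysis). Counterfactual (natural
direct/indirect) effect definitions and exposure–mediator interactions
are out of scope.

### Inference

Wald 95% intervals (estimate ± 1.959964·SE) accompany every fitted
equation. For the mediation estimands — which are products and
differences of coefficients from different equations — inference is by
a nonparametric percentile bootstrap: each replicate draws
`resample_size` rows with replacement from the analysis set (the
default run uses 10,000 rows and 5,000 replicates; both are config
keys), refits all three equations, and recomputes every requested
estimand. The 95% CI takes the 2.5th and 97.5th empirical percentiles
of the replicate vector, computed as order statistics ("lower" rule at
the lower end, "higher" at the upper end) so both endpoints are actual
replicate values. The bootstrap SE is the standard deviation of the
replicates. A difference in magnitude between two indirect effects is
declared when the CI excludes zero; the interval is treated as closed,
so an endpoint exactly at zero does not exclude it.

Replicates whose fits fail (e.g. separation in a resample) are dropped
and counted; more than 1% failures raises an error in strict mode and a
warning otherwise.

The raw difference is reported signed (a₁b₁ − a₂ᵢb₂ᵢ), with an
`absolute` mode available. Published tables in this literature
sometimes print the magnitude with an inconsistent sign; the package
always computes the signed definition and leaves interpretation of
magnitude to the `absolute` mode.

## Estimation details

Binary and multinomial logistic models are fitted by Newton–Raphson
(Fisher scoring) with step-halving, relative log-likelihood tolerance
1e-10, and at most 100 iterations; the gradient max-norm at the
reported optimum is below 1e-6. Perfect separation is detected by
coefficient divergence (‖β‖∞ > 40) and reported with the offending
term; rank-deficient designs raise an error rather than silently
dropping columns. Warm starts are supported and used by the bootstrap,
where refits from the full-data estimates typically converge in 2–4
iterations.

The random-intercept logistic likelihood integrates u_j out of each
cluster's likelihood by adaptive Gauss–Hermite quadrature: nodes are
recentred at the cluster's posterior mode (found by a damped,
deterministic inner Newton iteration) and rescaled by the local
curvature before the Hermite rule is applied. Seven quadrature points
are the default — the suite checks that doubling to 14 changes the
log-likelihood by less than 1e-6 — and the implementation agrees with
`lme4::glmer(..., nAGQ = 7)` to about 1e-6 on coefficients, σ² and
log-likelihood. The marginal likelihood is maximized over (β, σ) by
L-BFGS-B with an analytic gradient (the posterior-weighted
complete-data score, via the Fisher identity), σ bounded below by
zero. Standard errors come from a central-difference Hessian at the
optimum; the σ² SE uses the delta method from the σ parameterization.
When σ̂ hits the boundary, σ² is reported as 0 with an undefined SE and
fixed-effect uncertainty from the plain-logistic Hessian. `fix_sigma2`
pins the variance (0 reduces exactly to plain logistic, a nested-model
identity the tests exploit). With a single cluster the variance is
unidentified and the fit refuses to proceed.

AIC = 2k − 2L and BIC = k·ln(n) − 2L support the sequential model
ladder (exposure only → + covariates → + mediators as covariates → the
mediation model). Survey weights are intentionally unsupported: the
analysis this package reproduces did not apply them, prioritizing the
multilevel specification.

Rows with a missing M1 value are removed listwise before any model
involving the mediators; the loader logs the missing count.

## The synthetic cohort generator

Real microdata for this design (the 2018 Argentine National Risk
Factors Survey, ENFR) are available only on request, so the package
ships a generator that emulates the survey's structure and doubles as
first-class, tested code:

* **Provinces.** 24 provinces with annual mean temperatures spanning
  4.6–23 °C (the range reported for Argentina, south to north), on an
  equispaced grid by default or drawn uniformly at random. Individuals
  are assigned to provinces uniformly.
* **Covariates.** Sex, age and education are drawn from the published
  sample margins: 57.6% female; age truncated-Normal(46.1, 17.9²) on
  [18, 95] years; education shares 10.0/36.0/36.6/17.3% for incomplete
  primary / incomplete secondary / complete secondary / university.
* **Structural equations.** M1, M2 and the outcomes are drawn from the
  logistic/multinomial equations above. The default slopes are the
  fitted coefficients of the published analysis (a₁ = 0.020,
  a₂₁ = −0.015, a₂₂ = −0.059; b₁ = 0.025, b₂₁ = −0.168, b₂₂ = −0.362,
  c = −0.019 with σ² = 0.026 for overweight; b₁ = 0.018, b₂₁ = −0.234,
  b₂₂ = −0.413, c = −0.021 for obesity). Mediator-equation covariate
  effects default to zero (the published mediator blocks report only
  the temperature coefficient); the analysis still adjusts mediator
  equations for covariates by default, which is unbiased under the
  generator. The outcome covariate effects use the published adjusted
  model (female −0.365, age 0.029/year, education 0.269/0.317/0.208 vs
  university); the obesity equation reuses them, as no obesity-specific
  covariate block is published.
* **Random intercept.** One N(0, σ²) draw per province enters both
  outcome equations (shared provincial context); mediator equations
  exclude it by default, with a sensitivity switch (`ri_in_mediators`)
  to add it.
* **Intercepts.** The published analysis reports no intercepts, so they
  are calibrated: `marginal_prevalence` computes the population margin
  implied by a config by deterministic enumeration (provinces × sex ×
  education), Gauss–Legendre quadrature over age against the truncated
  normal density (41 nodes), exact enumeration of the six mediator
  combinations, and 31-point Gauss–Hermite quadrature over the random
  intercept — no sampling anywhere. `calibrate_intercepts` root-finds
  intercepts (Brent for the scalar equations, a 2-D Powell-hybrid solve
  for the two activity intercepts, which interact through the softmax)
  so the margins hit their targets to 1e-6. Default targets are the
  published sample margins: overweight 67.9%, activity low/moderate/high
  47/36/18%, fruit/vegetable adequacy 6% (the published table's
  fruit/vegetable row is typographically corrupted; 6% is the value the
  text supports). The obesity target, 32.4%, is the measured national
  obesity prevalence reported for the same survey wave.
* **Missingness.** M1 is masked completely at random at rate
  455/16,410 ≈ 2.77%, mirroring the published exclusion.
* **Reproducibility.** A single integer seed feeds a fixed, named list
  of `numpy` `SeedSequence` sub-streams (province temperatures,
  assignment, sex, age, education, intercepts, M1, M2, each outcome,
  missingness), so identical configs give bit-identical cohorts and
  adding a stage never perturbs earlier draws.

What the generator does **not** emulate: the survey's multistage
sampling design, strata and weights; within-province temperature
heterogeneity (each province is one scalar, so the mean-vs-median
temperature sensitivity switch is a no-op on synthetic data); any
latent BMI (overweight and obesity are drawn from separate equations
and are therefore not nested as real BMI cut-offs would be); and any
real spatial or socioeconomic confounding structure. Passing tests
therefore show that the pipeline recovers the data-generating process
it assumes — not that the published substantive estimates are correct.

Because only 24 random intercepts are drawn per cohort, empirical
outcome margins fluctuate around the analytic margin with a
between-province component ≈ (max expitʹ)²σ²/24 in addition to the
binomial term; generator/oracle agreement tests use this combined SE.

## Problem sizes and numerical choices

Simulation-based checks are sized to run on a single CPU in a few
minutes, chosen as the smallest sizes at which the checks are sharp:
structural-coefficient recovery uses ten cohorts of n = 16,000 (the
survey's scale) and compares means to generating values within 3
Monte-Carlo SEs; bootstrap coverage of the 95% percentile CI for the
high-activity indirect effect uses 200 datasets of n = 5,000 with 200
replicates each, fitting replicate outcome equations without the
random intercept (`quadrature_points=0`) — i.i.d. row resampling
breaks the cluster structure anyway, and at σ² = 0.026 the induced
attenuation (< 0.5%) is far below the estimand's sampling error. The
demo pipeline config (n = 5,000, 200 replicates of 2,000) completes in
well under five minutes.

Ties and degenerate inputs: a single province with `temp_min ==
temp_max` is valid (the midpoint); education probabilities must sum to
1 within 1e-12; calibration targets must lie strictly inside (0, 1) and
raise a calibration error when no root is bracketed in ±40 log-odds.

## Design choices that were genuinely open

* **Welch t-test by default** in the descriptive table (pooled-variance
  optional): the compared analysis reports only p-value magnitudes, and
  Welch is the safer default under unequal group variances.
* **Pearson chi-squared without continuity correction**, matching the
  large-sample contingency tables involved.
* **Percentile CI rather than BCa**: the reproduced analysis reports
  plain percentile endpoints and histograms of the bootstrap
  distribution.
* **Full-pipeline bootstrap** (refit all three equations per replicate)
  rather than coefficient perturbation: the estimand is a function of
  jointly re-estimated equations.
* **Covariates in mediator equations by default**, with
  `covariates_in_mediators=False` available, since published mediator
  blocks are ambiguous on this point.
* **Equation-by-equation ML** rather than one joint optimizer (exact,
  see above), which also makes warm-started bootstrap refits cheap.

## Known limitations

* Indirect effects are coefficient products on the log-odds scale;
  non-collapsibility of the odds ratio means they do not translate
  directly into risk differences.
* The bootstrap resamples individuals, not provinces; cluster-level
  uncertainty in σ² is reflected in the outcome-equation fit but not in
  the resampling scheme.
* No survey-weighted estimation, no random slopes, no crossed effects,
  no GEE/robust-sandwich variants.
* The obesity and overweight columns of a synthetic cohort are drawn
  independently given the mediators and may be logically inconsistent
  row by row; analyses use one outcome at a time.
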