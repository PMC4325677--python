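# Methods

This note documents the statistical models behind `mvmr`, the numerical
choices made in fitting them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where reasonable
alternatives existed.

## The causal model

There are J genetic variants (additive per-allele dosages g ∈ {0,1,2}), K
risk factors X₁…X_K and an outcome Y.  Variants may be associated with any
subset of the risk factors (pleiotropy), but must not affect the outcome
through any path not mediated by the modelled risk factors, must not be
associated with confounders, and all relationships are linear.  Under these
assumptions the parameters β₁…β_K are the *controlled direct effects*: the
effect of intervening on one risk factor while holding the others fixed.
When risk factors affect each other, the direct effect differs from the
total effect; `total_effect` converts between them by path accumulation,
t = (I − Aᵀ)⁻¹β for an acyclic dependence matrix A (A[k,l] = effect of
factor l on factor k).

## Individual-level estimation (2SLS)

First stage: multivariate OLS of the n×K risk-factor matrix on [1, G];
second stage: OLS of y on [1, X̂].  Point estimates equal this sequential
solution, but the reported variance is σ̂²(X̂ᵀX̂)⁻¹ with σ̂² computed from
y − Xβ̂ using the *original* risk factors on n−K−1 degrees of freedom — the
correction dedicated IV software applies.  Both stages include intercepts.
A heteroskedasticity-robust (sandwich) variance is available behind
`robust=True` but is not the default.  J = K (just identified) is allowed;
J < K raises an identification error rather than silently dropping
exposures.  Estimates are invariant to any invertible linear recoding of
the instruments (e.g. allele flips), which the test suite checks.

The *sequential adjustment* comparator instruments each risk factor in turn
with the other K−1 factors entered as exogenous covariates in both stages.
Conditioning on heritable, confounded covariates opens non-causal paths, so
the method is biased even for truly-null effects, with direction set by the
confounders; it exists only so this bias can be demonstrated, and its
output is flagged accordingly.  All variants (not an allele score) are used
as instruments in each single-factor fit.

## Summarized-data likelihood

Observed per-variant betas (β̂_X·j, β̂_Yj) are modelled as (K+1)-variate
normal around (ξ·j, βᵀξ·j) with covariance Σ_j[a,b] = ρ_ab σ_aj σ_bj, where
σ are the reported standard errors and ρ the between-trait correlations of
the estimates.  With full sample overlap ρ is approximately the
observational trait correlation matrix; with no overlap the
exposure–outcome entries are zero.  ρ is shared across variants.  The model
has K(J+1) parameters; its K-dimensional structural part is identified when
J ≥ K.

**Maximisation.** For fixed β the log-likelihood is an exact GLS problem in
each ξ·j (design [I_K; βᵀ]), solved in closed form per variant.  The outer
optimisation therefore runs over the K-dimensional profile likelihood only
(Nelder–Mead, then BFGS polish from the Nelder–Mead point; started at the
multivariable IVW solution).  This avoids fragile joint optimisation over
all K(J+1) parameters (87 for J=28, K=3).

**Standard errors.** The Hessian of the negative profile log-likelihood at
β̂ (central differences, relative step 1e-4) is inverted.  By the standard
profile-likelihood identity this equals the β-block of the inverse full
observed information, so the SEs correctly account for estimating ξ.
Intervals are Wald at a default 95% level.

**Limits.** As the exposure-beta SEs vanish with ρ = I, the model collapses
to weighted least squares of β̂_Y on the β̂_X columns with weights 1/σ_Y²
and no intercept — the multivariable IVW estimator — which the tests verify
to 1e-6.  With a single variant and factor, the Bayesian posterior
concentrates on the Wald ratio β̂_Y/β̂_X.

**Linkage disequilibrium.** Correlated variants violate the independent
per-variant factorisation; the LD-aware fit stacks all J(K+1) betas into
one multivariate normal with Cov[(j,a),(j′,b)] = ρ^LD_jj′ · ρ_ab · σ_aj ·
σ_bj′.  Only the within-trait case (b = a) is forced by theory; the
separable cross-trait extension is the natural completion and is an
assumption of this implementation.  With ρ^LD = I the stacked model reduces
exactly to the independent fit (block-diagonal covariance).  A singular
stacked covariance (e.g. duplicated variants) raises an error; eigenvalue
clipping is offered as an explicit `clip_psd=True` option, never silently.
Note that the correctly specified LD model can be *more* efficient than the
independent-variant fit; the reason to use it is calibration — under LD the
independent fit's reported SEs no longer track its sampling variability, so
its intervals are unreliable (the test suite demonstrates a reported-SE to
empirical-SD ratio of ~0.75 under equicorrelation 0.4).

**Bayesian fit.** Independent N(0, s₀²) priors (default s₀ = 10) on every ξ
and β.  Both full conditionals are Gaussian — ξ·j | β is a K-variate GLS
posterior (independent across variants), and β | ξ is K-variate Gaussian
because the outcome mean is linear in β — so a blocked Gibbs sampler needs
no tuning, mixes rapidly, and is exactly reproducible under a seed.
Defaults: 4 chains, 500 warm-up + 2000 retained draws each (minimum 100);
convergence monitored by split-chain R̂ per causal effect, with R̂ > 1.05
recorded as a warning in the diagnostics.  In well-identified problems the
posterior mean matches the MLE closely; under weak identification the
posterior is skewed and its mean can sit a noticeable fraction of a
posterior SD from the joint mode — that is a property of the model, not a
sampler artefact.

**Regression-based comparator.** Stage 1: OLS of β̂_Y on the competing
factors' beta columns; stage 2: OLS of the stage-1 residuals on the target
factor's betas, reporting the stage-2 slope with its naive OLS SE.  Both
stages include intercepts by default (guarding against mean offsets; a
no-intercept option exists for sensitivity).  The method ignores the
uncertainty in the betas and has no clear theoretical basis; it is
reproduced faithfully and flagged as an ad hoc comparator.  Its estimates
are biased toward the null in typical settings, and its power is poor.

**Scale conventions.** Binary-outcome inputs are consumed as given log odds
ratios or log relative risks; the causal effects inherit that scale.  For
log-transformed exposure concentrations, the odds ratio per (100·f)%
reduction is exp(β̂ · ln(1 − f)); interval endpoints map monotonically
(decreasing in β̂).

## Synthetic-data generator

Genotypes are i.i.d. Binomial(2, maf) with maf 0.3 — independent variants,
Hardy–Weinberg, no LD, no population structure.  Risk factor k is an
additive genetic component plus a leave-one-out confounder load (confounder
k affects every risk factor *except* k, and the outcome), optional causal
contributions from upstream risk factors (evaluated in dependency order),
and unit-variance normal noise.  The outcome is linear:
y = Σ β_Uk u_k + Σ β_k x_k + ε.  Defaults are the base study conditions:
n = 30,000, J = 28, K = 3, direct effects (0.3, 0, −0.1), all confounder
effects 0.3, unit noise.

Per-variant genetic effect sizes are a packaged *synthetic* pattern: a
fixed seeded draw of pleiotropic loadings, column-rescaled so the aggregate
first-stage sample R² per risk factor hits (0.6%, 0.5%, 3.2%) at
n = 30,000 — i.e. mean F near (6.6, 5.2, 35.4): two weak sets of
instruments and one strong, the regime typical of lipid genetics.  Targets
are interpreted as expected *sample* R² from the J-regressor fit, which
exceeds the population R² by ≈ (1−R²)·J/(n−1); the generator
back-corrects.  Real per-variant effect tables can be supplied directly on
the scenario (`alpha_G`) or via the scenario YAML.

What the generator does **not** emulate: linkage disequilibrium between
variants, non-normal risk-factor or outcome distributions, binary outcomes
(the outcome model is linear throughout; logistic simulation is out of
scope), genotype–covariate interactions (except the optional
`interaction_scale` misspecification probe, which adds pairwise
genotype-product terms to the risk factors), assortative mating, selection,
or missing data.  Passing tests therefore demonstrate correctness of the
estimators under their stated assumptions, not robustness to these
real-data features.

## Monte-Carlo execution

Replicate r of a scenario uses `SeedSequence(entropy=seed, spawn_key=(r,
0))` (and `(r, 1)` for the independent two-sample dataset), so replicates
are independent, individually re-runnable and bit-reproducible.  Power is
the share of replicates with |estimate/SE| > 1.96 (Wald test at nominal
5%); its Monte-Carlo SE is the binomial √(p(1−p)/reps), and the mean
estimate's MC SE is SD/√reps.  Summary methods re-estimate trait
correlations inside each replicate (one-sample setting); two-sample mode
takes outcome associations from an independent replicate and zeroes the
exposure–outcome correlation entries.  Estimator failures in a replicate
are logged and excluded, never averaged, with the exclusion count reported.

Weak-instrument behaviour: the one-sample bias toward the confounded
observational association is a property of estimators that take the
exposure betas at face value (2SLS, IVW); the two-sample design replaces it
with dilution toward the null.  The errors-in-variables likelihood largely
corrects the dilution when the supplied σ_X and ρ are accurate, so the
bias-direction demonstrations in the test suite use 2SLS/IVW.  Under
extremely weak instruments (F ≲ 2) the ML surface can be nearly flat or
multimodal; non-convergence raises an error (counted as a failure in
scenario runs) rather than returning a dubious optimum.

## Problem sizes used in the checks

The shipped statistical checks run at n = 5,000–30,000 subjects and
150–1,000 replicates per claim — sizes chosen so Monte-Carlo SEs (≈0.003–
0.008 on mean estimates, ≈0.7% on power) are small relative to the effects
being demonstrated.  The nominal-size check uses genetic effects rescaled
so every first-stage F is ≈50 at n = 5,000, making weak-instrument bias
negligible by design.

## Known limitations

* Weak-instrument-robust individual-level estimators (LIML, Fuller) are not
  implemented.
* No allele harmonization, VCF/PLINK parsing or proxy-variant lookup: the
  caller must orient all associations to the same effect allele.
* Missing data are rejected, not imputed.
* The trait-correlation matrix is shared across variants; the modified
  regression-based method with improved properties is out of scope.
* Univariate summarization regressions adjust for nothing beyond the
  intercept; covariate-adjusted GWAS inputs are consumed as given.
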