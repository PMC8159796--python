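# Methods

## Structural model

All data are generated from a linear Gaussian structural equation system.
With instrument scores G (independent standard normal, or standardised
unweighted allele scores over k biallelic SNP dosage columns in `snps` mode),
a shared standard-normal confounder U and an exposure-caused intermediate
confounder L:

```
X    = mu_X + gamma_X G_X + u_X U + sd_X e_X
L    = lambda_L X + sd_L e_L
M_j  = mu_Mj + a_j X + sum_i d_ij M_i + gamma_Mj G_Mj + u_Mj U + l_Mj L + sd_Mj e_Mj
eta  = c' X + sum_j b_j M_j + theta X M_1 + u_Y U + l_Y L
       + p_X G_X + sum_j p_Mj G_Mj + sd_Y e_Y
Y    = eta                         (continuous)
Y    = Bernoulli(expit(b0 + eta))  (binary)
```

Every bias mechanism is one knob: confounder loadings (u), intermediate
confounding (lambda, l), classical additive measurement error applied to the
observed exposure/mediators after all structural equations, direct
instrument→outcome paths (p, pleiotropy), first-stage coefficients gamma
(weak instruments), the interaction theta, and directed mediator→mediator
chain edges d (acyclic, validated by topological sort).

True effects are obtained by path tracing: the total effect of X on mediator
j is T_j = a_j + Σ_i d_ij T_i in topological order, the indirect effect
through j is T_j·b_j, the combined indirect effect is the sum over
mediators, and total = c' + combined indirect (exact by construction). With
theta ≠ 0 there is no single linear estimand and `true_effects` refuses.

## Binary outcomes

The binary link is logistic; the intercept b0 is solved by bisection on the
sampled linear predictor so the realised prevalence hits the target (defaults
follow the 5% rare / 25% common convention). Because eta and every
instrument/phenotype are jointly Gaussian, Stein's lemma gives
cov(Y, Z) = E[p(1−p)]·cov(eta, Z) for any linear combination Z of model
variables, so **every linear-regression or 2SLS estimand on the binary
outcome equals k times its structural log-odds counterpart**, with
k = E[p(1−p)] computed by 101-node Gauss–Hermite quadrature from the
model-implied Var(eta). This gives exact risk-difference-scale truths (the
proportion mediated is scale-free), which is what makes unbiasedness of the
risk-difference MR decomposition a testable statement. Log-odds-scale IV
estimation uses two-stage predictor substitution and is *expected* to carry
a small non-collapsibility bias that grows with the true proportion
mediated — the implementation reproduces that behaviour rather than
correcting it, and the odds-ratio scale (exponentiated log-odds) is flagged
as known-biased.

## Estimators

OLS and 2SLS are solved on the normal equations (Cholesky with an explicit
rank check) because the Monte-Carlo layers fit ~10^5 small regressions; the
2SLS covariance uses residuals from the observed exposures at the
second-stage estimates (textbook IV variance; cross-checked against the
statsmodels IV implementation in the tests). Homoskedastic SEs by default,
HC0 sandwich as an option; no small-sample df corrections beyond n−k.
Logistic fits delegate to statsmodels ML, with no outcome variation, rank
deficiency, non-convergence and perfect separation all surfaced as
degenerate-fit errors.

Instrument strength: the joint first-stage F, and for multivariable models
the Sanderson–Windmeijer conditional F — the target exposure is regressed on
the other exposures by 2SLS, and the instruments' F is computed on those
residuals with numerator df (#instruments − #other exposures) and denominator
df (n − #instruments − #other exposures). In the orthogonal case this
reproduces the marginal F; with near-collinear instrument sets it collapses
toward zero. Anything below 10 trips the weak-instrument flag.

Two-step MR always uses the multivariable second step (exposure and mediator
jointly instrumented), so the mediator→outcome effect is conditional on the
exposure and a direct-effect estimate comes for free. Instrument sets for
exposure and mediator must be disjoint — shared identifiers are a hard error
because an attenuation of the direct effect then cannot be distinguished
from pleiotropy — and disjoint-but-highly-correlated score columns
(|r| > 0.9 by default) raise a warning.

## Proportion mediated and bootstrap

PM = indirect/total; undefined (None + warning) at total = 0, warned when
|total|/SE < 2 or when direct and indirect oppose in sign — configurable
thresholds, since only qualitative caution is established practice. CIs are
nonparametric percentile bootstrap over whole individuals (joint resampling
of both steps, natural in the one-sample setting; BCa was not needed at the
sample sizes targeted). Degenerate resamples are skipped and counted; >10%
skipped raises a warning. Measured coverage for the indirect effect in a
confounded strong-instrument scenario (n = 2500, 250 draws, 500 replicates)
is ~94% for the nominal 95%.

## Study conditions and defaults

Defaults follow the simulation design the estimators are studied under:
n = 5000 per cohort; single shared confounder with loadings 0.5 on exposure,
mediators and outcome in confounded scenarios; unit residual SDs;
strong polygenic-score instruments gamma = 1 (first-stage F ≫ 10) except in
the weak-instrument presets, where gamma is set from
E[F] ≈ 1 + n·gamma²·Var(G)/(q·Var(residual)) to a target F < 10 and the SNP
mode (q = 10) is used so the over-identified estimator has finite moments
and mean-bias tables are well defined. Effect-size grids fix the
mediator→outcome path at b = 0.5 and derive a = PM·total/b,
c' = total·(1−PM) for total ∈ {0.2, 0.5, 1.0} × PM ∈ {0.1, 0.25, 0.5}.
Desk-scale runs use 200 replicates (full-scale 1000 behind a flag); each
replicate draws its RNG stream from (master seed, replicate index), so grids
are reproducible and parallelisable.

Two scenario families needed design choices of their own:

* **Measurement error.** The ME presets run without confounding to isolate
  the mechanism, with a mediator strongly determined by the exposure
  (a = 1.0, b = 0.25, c' = 0.25, gamma_M = 0.3, sd_M = 0.3). There, mediator
  error attenuates the mediator→outcome coefficient (mediated effect
  under-estimated) while exposure error lets the mediator proxy the
  mismeasured exposure and absorb direct-effect signal (mediated effect
  over-estimated). The exposure-error direction is parameterisation-
  dependent: with a weakly coupled mediator the attenuation of a dominates
  and the mediated effect is under-estimated instead.
* **Interaction.** With all variables zero-mean Gaussian, X·M is
  uncorrelated with X and M (odd moments vanish) and no linear coefficient
  moves; the interaction preset therefore sets E[M] = 1, giving a
  direct-effect bias of theta·E[M] in both difference-type methods,
  monotone in theta.

## Oracles

`plim_noniv_oracle` writes every model variable as a linear combination of
independent unit-variance shocks, forms the exact model-implied covariance
matrix, and solves the population normal equations — the probability limit
of any OLS coefficient vector, including omitted-variable and
measurement-error bias (continuous outcomes, theta = 0). Monte-Carlo means
of the non-IV estimators are tested against these limits; MR estimators are
tested against the path-traced truths. In tests, an independent
path-enumeration oracle (all simple paths of the effect DAG) checks the
path tracing, and statsmodels' IV2SLS checks the 2SLS algebra.

## Numerical choices and degenerate inputs

Rank checks precede every solve (duplicated columns and constant regressors
raise rather than return garbage); the binary intercept search brackets
[−40, 40] and reports the achieved prevalence on failure; bootstrap
percentiles ignore skipped resamples; per-replicate estimation failures in
study grids are counted and tolerated up to 10%, beyond which the scenario
aborts. Scale tags are validated against the outcome type (a linear request
on a binary outcome must be made explicitly as risk difference).

## Limitations

The generator is linear-Gaussian with a logistic binary link: it emulates
confounding structure, instrument strength and error processes, not
real-cohort features such as non-normal phenotypes, heteroskedasticity,
assortative mating or population stratification — passing tests demonstrate
estimator algebra and bias mechanics, not robustness to those. Binary
exposures/mediators are not supported as estimands (liability dichotomisation
violates the exclusion restriction; only causal-null testing would be
meaningful). Summary-statistics (two-sample) MR, delta-method CIs,
pleiotropy-robust estimators (Egger/median/mode) and
counterfactual estimators accommodating exposure–mediator interaction are
out of scope. The proportion mediated is a plug-in ratio and carries an
O(1/n) positive bias when the total effect is small relative to its SE — the
small-total warnings exist precisely because point estimates there are
fragile.
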