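# Methods

## Model

Patients i are nested in hospital departments j. The outcome y_ij is
death within one year of diagnosis (binary). The step-2 model is a
random-intercept logistic regression

logit P(y_ij = 1) = **x**_ij' **β** + u_j,  u_j ~ N(0, σ²),

with department effects assumed normal on the logit scale, independent
of the covariates, and (in the main specification) common slopes across
departments. Step 1 is the same model without u_j. The general
contextual effect of the department is read jointly from

* **ICC (latent-response method)** = σ² / (σ² + π²/3). The logistic
  residual is assigned the variance of a standard logistic distribution,
  π²/3 ≈ 3.2899, so the ICC is the correlation in the latent propensity
  between two patients of the same department. It is strictly increasing
  in σ² and maps [0, ∞) into [0, 1).
* **ΔAUC**: the AUC of the discriminator **x**'β̂ + û_j minus the AUC of
  **x**'β̂. Adding cluster residuals can only exploit between-department
  signal, so under homogeneity ΔAUC ≈ 0.

Both are computed in-sample, matching audit practice; cross-validated
discrimination is out of scope.

## Estimation

**Maximum likelihood (default).** The marginal likelihood integrates
each department's conditional likelihood against N(0, σ²). The integral
is evaluated by adaptive Gauss–Hermite quadrature: per cluster, the
integrand's mode is found by a vectorised Newton iteration and the
quadrature grid is centred and scaled by the mode and curvature; 15
nodes by default, doubled automatically if the log-likelihood at the
optimum moves by more than 1e-4 under node doubling. The optimiser
(L-BFGS-B) works on (β, log σ²) to keep the variance positive, with
relative log-likelihood tolerance 1e-8. Standard errors come from the
numerical Hessian at the optimum; the 95% interval for σ² is Wald on
log σ² (profile-likelihood intervals are a non-goal). Estimates with
σ̂² below 1e-5 — where the profile in log σ² is flat — are reported as
boundary solutions: σ̂² = 0, all residuals exactly 0 with zero-width
intervals, and a warning. Against `lme4::glmer` (nAGQ = 15) the fitted
β, σ̂² and log-likelihood agree to ~1e-3 or better on test fixtures.

**MCMC.** Metropolis-within-Gibbs: the cluster intercepts are updated
by vectorised random-walk Metropolis (one proposal per cluster per
sweep), the fixed effects componentwise by random-walk Metropolis, and
σ² by its conjugate draw. Proposal scales adapt during burn-in toward
0.44 acceptance (Robbins–Monro, batch size 50). Starting values come
from the ML fit. Priors: β ~ N(0, 10⁶); σ² ~ inverse-gamma(0.001,
0.001), with a uniform-on-σ alternative exposed because the
inverse-gamma is influential when σ² is near zero. Chain defaults are
deliberately long (5,000 burn-in, 50,000 iterations, thin 10) because
the variances of interest sit near the boundary; tests use shorter,
validated chains. σ² is summarised as the posterior median (mean also
stored) with 2.5/97.5-percentile credible intervals; mixing is screened
by split-R̂ of the σ² chain over four segments (warning above 1.1).

**DIC** uses the conditional deviance D(β, u) = −2 Σ log p(y | β, u):
DIC = D̄ + pD with pD = D̄ − D(β̄, ū) at posterior means. The
single-level comparator is fitted with the same sampler minus the
random effects so the two DICs are on the same footing.

**Shrunken residuals.** ML path: empirical-Bayes posterior means and
SDs of u_j at (β̂, σ̂²), computed with the same adaptive quadrature; CIs
are ±1.96·SD. MCMC path: posterior means/SDs of the u_j draws (1.96·SD
bands by default; percentile bands can be formed from the stored
draws). Small departments shrink strongly toward 0 — this is the
league-table input, ranked ascending.

**ICC intervals** are formed either by mapping the variance-interval
endpoints through the (monotone) ICC formula, or by transforming each
posterior draw and taking percentiles. The reported point estimate is
ICC-of-the-variance-point-estimate; the posterior-median-of-ICC
convention is also computed, since the two can differ in the last
printed decimal when the posterior is skewed.

**AUC** is the Mann–Whitney rank estimator (ties ½), O(n log n), with a
DeLong midrank variance for the CI; a perfectly separating score gives
SE 0 and is flagged degenerate. DeLong (rather than bootstrap) is the
declared default: deterministic and fast.

## Supporting checks

* **Three-level screen**: an intercept-only model with nested
  department and hospital intercepts (MCMC only); variance partition
  coefficients put both variances plus π²/3 in the denominator. The
  pipeline proceeds two-level when the hospital share is below 1% — a
  declared numeric rule for "very small hospital variance"; both
  variances are always reported so the user can override.
* **Quadratic age**: refit with centred age and its square; the square
  is kept only if its Wald p < 0.05.
* **Random slope**: bivariate (intercept, slope) department effects
  with an inverse-Wishart(ν₀ = 3, S = 10⁻³·I) prior on the 2×2
  covariance. Slope variation is "not substantive" when the slope
  variance's 95% credible lower bound is below 0.001 *and* DIC does not
  improve by more than 2. The prior scale must sit below the 0.001
  threshold or the rule could never fire; DIC Monte-Carlo error must be
  well under the ±2 band, which needs chains of roughly 12k iterations
  at the test problem sizes.

## Synthetic registers

`generate_cohort` draws from exactly the step-2 generative model plus
an optional hospital level: department sizes from a symmetric
Dirichlet (concentration 5) scaled to n and largest-remainder rounded,
departments assigned to hospitals with each hospital covered; ages
truncated-normal (SD 9 by default — registers publish only medians) in
the preset inclusion windows (≥18, or 45–80); sex Bernoulli;
K independent Bernoulli comorbidity indicators; outcome Bernoulli of
the inverse-logit linear predictor. One `numpy` Generator stream per
(spec, seed) makes cohorts byte-reproducible.

Preset intercepts were calibrated once by Monte-Carlo bisection (10⁶
draws) to the target marginal mortalities (0.13 and 0.22) and frozen,
because the marginal mean of a logistic random-intercept model has no
closed form. The `swedish_like` comorbidity prevalences (0.04–0.35) and
log-ORs (0.10–0.50) are fixed plausible values chosen to produce the
familiar steep mortality gradient across risk-score deciles; the
per-year age effect is OR 1.08 (`danish_like`) / 1.04 (`swedish_like`)
and the female effect OR 1.0 / 0.85.

What the generator does **not** emulate: correlated comorbidities,
non-normal or covariate-dependent department effects, within-department
time trends, missing data, the inpatient/outpatient case mix of
incident-HF registers, and differing outcome clocks (first contact vs
discharge). Passing tests therefore certify the estimation machinery
under the stated model, not the registers' full data-generating
process.

## Numerical and design choices

* Age is centred at the cohort mean before fitting (stable intercept;
  per-year ORs unaffected). OR tables use Wald intervals on the log
  scale, rendered to two decimals.
* Separation is reported, not penalised (no Firth correction):
  coefficients exceeding |β| > 15 flag the fit non-converged with a
  diagnostic warning.
* The risk score is refit on the cohort-year it adjusts, from the
  comorbidity indicators only; deciles are quantile bins with ties to
  the lower bin; deciles 2–10 enter the models as indicators, while the
  random-slope check uses the centred continuous score.
* Periods are analysed independently (annual profiling); no pooling.
* League-table CIs are per-department, not multiplicity-adjusted
  (stated in the report footer).
* Empty clusters are dropped with a warning; singleton clusters are
  allowed and shrink heavily.

## Problem sizes used in validation

Parameter recovery uses 20 seeds of 200 clusters × 50 patients at
σ² = 0.115 (mean σ̂² within ±0.03, ≥90% interval coverage); null
calibration and GCE detection use 20 seeds at the `danish_like` scale
with σ² = 0 and 1 respectively; DIC ordering uses 20 seeds of 40 × 50
at ICC 20% with 3,600-iteration chains; the three-level and
random-slope checks use 30 hospitals × 5 departments × 40 patients and
50–100 clusters × 60 patients. These sizes are the package's own
validation choices; the estimators themselves have no size limits
beyond memory.

## Known limitations

* ML variance intervals are Wald-on-log-σ² and can be poor near the
  boundary; prefer the MCMC credible intervals there.
* The MCMC sampler is single-chain (split-R̂ on segments); for
  publication-grade inference run multiple seeds.
* In-sample ΔAUC is optimistically biased in small clusters (the
  residuals are estimated from the same data they then discriminate);
  the null-calibration tests bound this spurious gain at the register
  scales exercised.
* The three-level screen reports variance partition coefficients, not
  pairwise intra-unit correlations; with both levels present the
  department VPC understates the total same-department correlation.
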