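# gceprofiler

Multilevel analysis of individual heterogeneity for profiling hospital
departments on a binary patient outcome (one-year mortality after a
heart-failure diagnosis).

## The problem

National quality audits routinely rank hospital departments by their
average one-year mortality. Such league tables are only meaningful if
the department actually conditions patient outcomes — that is, if a
non-trivial share of the patient-level heterogeneity sits *between*
departments. `gceprofiler` quantifies this **general contextual effect
(GCE)** with a two-step regression analysis:

1. **Step 1 — single-level logistic regression** on patient
   characteristics only (sex, age, and for case-mix-rich registers a
   comorbidity risk score entered as decile indicators), with its AUC.
2. **Step 2 — two-level random-intercept logistic regression** with
   patients nested in departments:

   logit P(y_ij = 1) = **x**_ij' **β** + u_j,  u_j ~ N(0, σ²)

   From this model it reports:
   * the **ICC** by the latent-response method,
     ICC = σ² / (σ² + π²/3), the correlation in the latent propensity
     of death between two patients of the same department;
   * the **AUC** of the prediction equation *including* the department
     residuals û_j, and **ΔAUC** versus step 1;
   * **DIC** (MCMC path) for model comparison;
   * **shrunken (empirical-Bayes) residuals** û_j with 95% CIs — the
     league table.

A small ICC together with a small ΔAUC means departments perform
homogeneously and ranking them is statistical noise; a large GCE
justifies a full case-mix-adjusted profiling analysis.

Estimation is by adaptive Gauss–Hermite quadrature maximum likelihood
(`method="ml"`) or by Metropolis-within-Gibbs MCMC with a conjugate
inverse-gamma variance draw (`method="mcmc"`), which reports the
posterior median and 95% credible interval of σ² and the DIC.
Supporting checks mirror the exploratory workflow: a three-level empty
model (patients in departments in hospitals) to screen the hospital
level, a quadratic-age linearity check, and a random-slope check for
whether a case-mix adjuster acts uniformly across departments.

Because the underlying patient registers are not public, the package
ships a synthetic-cohort generator (`gceprofiler.cohorts`) that draws
register-like cohorts from a random-intercept logistic model with known
department variance — two presets emulate an incident-heart-failure
audit register (`danish_like`: ~4,000 patients/year, 40 departments, 32
hospitals, mortality ≈ 13%) and a first-hospitalisation register
(`swedish_like`: ~12,000 patients/year, 450 departments, 71 hospitals,
mortality ≈ 22%, 18 comorbidity indicators).

## Worked example

The ICC calculator applied to a department-level variance of 0.115:

```
$ gceprofiler icc 0.115
3.4%
$ gceprofiler icc 0.115 --ci 0.027 0.281
3.4% (0.8–7.9)
```

i.e. 3.4% of the latent patient heterogeneity in death propensity sits
between departments — a small general contextual effect.

Simulate an audit-register-like cohort and profile it end to end:

```
$ gceprofiler simulate --preset danish_like --seed 7 --out sim
wrote sim/cohort.csv (4000 patients, 40 departments, mortality 0.119)
$ gceprofiler profile sim/cohort.csv --covariates danish --method ml --out prof
ICC 1.4%  delta-AUC 0.014  (40 departments, 4000 patients)
outputs in prof/
```

This run generated the cohort with σ² = 0.115 (preset truth) and
estimated σ̂² = 0.046 from its 40 departments (single-realisation
sampling noise at J = 40 is large; across seeds the estimator is
unbiased — see the test suite). The report says: departments explain
1.4% of the latent heterogeneity and knowing the department improves
in-sample discrimination by 0.014 AUC units — homogeneous performance,
no grounds for ranking. `prof/` contains `gce_report.json` (both
models' AUCs with DeLong CIs, OR tables, σ² with interval, ICC, DIC or
log-likelihood), `league_table.csv` (departments ordered by shrunken
residual with 95% CIs and an overlaps-reference flag), a caterpillar
plot with its plot-data CSV, and a run manifest.

The same objects are available as a library — scikit-learn-style
estimators with thin functional wrappers:

```python
from gceprofiler import (preset_spec, generate_cohort, run_two_step,
                         ProfilingConfig, league_table)

cohort = generate_cohort(preset_spec("swedish_like"), seed=7)
report, fit2 = run_two_step(cohort, ProfilingConfig(covariate_set="swedish",
                                                    method="ml"))
print(report.icc["percent"], report.delta_auc)
table = league_table(fit2)
```

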