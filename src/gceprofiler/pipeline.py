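"""End-to-end annual profiling of hospital departments.

Orchestrates, per cohort-year: case-mix risk-score construction, the
single-level step-1 model, the department random-intercept step-2
model, the general-contextual-effect measures (ICC, AUC with and
without random effects, delta-AUC, DIC) and a shrunken-residual league
table with caterpillar-plot artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import glm, metrics, mlm
from .cohorts import Cohort

__all__ = [
    "RiskScore",
    "ProfilingConfig",
    "GCEReport",
    "build_risk_score",
    "run_two_step",
    "league_table",
    "render_caterpillar",
]


@dataclass
class RiskScore:
    """Per-patient case-mix risk score with decile grouping.

    The score is the predicted death probability from a single-level
    logistic model on pre-admission diagnosis indicators only (no
    age/sex — those enter the profiling models separately); decile
    group 1 is the lowest risk, ties go to the lower bin.
    """

    rs: np.ndarray
    decile_group: np.ndarray
    model: glm.SingleLevelLogistic
    dropped_columns: list[str] = field(default_factory=list)


def build_risk_score(cohort: Cohort, diagnosis_columns: list[str] | None = None) -> RiskScore:
    """Fit the case-mix model and bin patients into risk-score deciles."""
    df = cohort.data
    if diagnosis_columns is None:
        diagnosis_columns = cohort.comorbidity_columns
    if not diagnosis_columns:
        raise ValueError("no diagnosis columns to build a risk score from")
    missing = [c for c in diagnosis_columns if c not in df.columns]
    if missing:
        raise ValueError(f"diagnosis column(s) not in cohort: {missing}")
    X = df[diagnosis_columns].copy()
    dropped = [c for c in diagnosis_columns if X[c].nunique() == 1]
    if dropped:
        warnings.warn(f"dropping constant diagnosis column(s): {dropped}", UserWarning)
        X = X.drop(columns=dropped)
        if X.shape[1] == 0:
            raise ValueError("all diagnosis columns constant")
    bad = [c for c in X.columns if not X[c].isin([0, 1]).all()]
    if bad:
        raise ValueError(f"diagnosis column(s) not binary: {bad}")
    fit = glm.SingleLevelLogistic().fit(X, df["outcome"].to_numpy())
    rs = fit.predict_proba(X)
    thresholds = np.quantile(rs, np.arange(1, 10) / 10.0)
    decile = 1 + np.searchsorted(thresholds, rs, side="left")
    return RiskScore(rs=rs, decile_group=decile.astype(int), model=fit,
                     dropped_columns=dropped)


@dataclass
class ProfilingConfig:
    """What to fit and how.

    ``covariate_set``: ``danish`` (female + age), ``swedish`` (female +
    age + risk-score decile indicators) or ``custom`` with
    ``custom_terms`` naming cohort columns.  ``method`` selects the
    step-2 estimator.  The optional checks mirror the exploratory
    phase: quadratic-age linearity, the three-level hospital screen,
    and the random-slope check on the centred continuous risk score.
    """

    covariate_set: str = "danish"
    custom_terms: list[str] = field(default_factory=list)
    method: str = "ml"
    mcmc: mlm.McmcConfig = field(default_factory=mlm.McmcConfig)
    check_quadratic_age: bool = True
    check_three_level: bool = False
    check_random_slope: bool = False
    three_level_icc_threshold: float = 0.01
    period_label: str = ""

    @classmethod
    def from_dict(cls, d: dict) -> "ProfilingConfig":
        d = dict(d)
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = mlm.McmcConfig(**d["mcmc"])
        checks = d.pop("checks", None)
        if checks:
            d.setdefault("check_quadratic_age", checks.get("quadratic_age", True))
            d.setdefault("check_three_level", checks.get("three_level", False))
            d.setdefault("check_random_slope", checks.get("random_slope", False))
        return cls(**d)


@dataclass
class GCEReport:
    """Everything an annual evaluation reports, serialisable to JSON."""

    period: str
    n_patients: int
    n_departments: int
    covariate_set: str
    method: str
    model1: dict
    model2: dict
    delta_auc: float
    icc: dict
    age_linearity: dict | None = None
    random_slope: dict | None = None
    three_level: dict | None = None
    terms: list[str] = field(default_factory=list)
    footer: str = ("League-table 95% CIs are per-department and not adjusted "
                   "for multiple comparisons.")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_json_default, **kwargs)
        if path is not None:
            Path(path).write_text(text)
        return text


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, mlm.McmcConfig):
        return dataclasses.asdict(o)
    return str(o)


def _design_for(cohort: Cohort, config: ProfilingConfig) -> tuple[pd.DataFrame, RiskScore | None]:
    df = cohort.data
    if config.covariate_set == "danish":
        return df[["female", "age"]].astype(float), None
    if config.covariate_set == "swedish":
        score = build_risk_score(cohort)
        X = df[["female", "age"]].astype(float).copy()
        for d in range(2, 11):  # decile 1 is the reference
            X[f"rs_decile_{d}"] = (score.decile_group == d).astype(float)
        return X, score
    if config.covariate_set == "custom":
        missing = [c for c in config.custom_terms if c not in df.columns]
        if missing:
            raise ValueError(f"custom term(s) not in cohort: {missing}")
        return df[config.custom_terms].astype(float), None
    raise ValueError("covariate_set must be 'danish', 'swedish' or 'custom'")


def run_two_step(cohort: Cohort, config: ProfilingConfig | dict | None = None):
    """The two-step analysis of one cohort-year.

    Step 1 fits the patient-only single-level model and its AUC; step 2
    adds the department random intercept and reads the general
    contextual effect off the ICC and the AUC gain when department
    residuals enter the prediction equation.  Returns
    ``(GCEReport, step2_fit)`` so the league table can be built from
    the same fit.
    """
    if config is None:
        config = ProfilingConfig()
    elif isinstance(config, dict):
        config = ProfilingConfig.from_dict(config)
    df = cohort.data
    y = df["outcome"].to_numpy()
    groups = df["dept_id"].to_numpy()

    X, score = _design_for(cohort, config)
    # centre age for a stable intercept; per-year ORs are unaffected
    X = X.copy()
    if "age" in X.columns:
        X["age"] = X["age"] - X["age"].mean()

    age_decision = None
    if config.check_quadratic_age and "age" in X.columns:
        d = glm.check_quadratic_age(X, y, "age")
        age_decision = {"keep_quadratic": d.keep_quadratic, "wald_p": d.wald_p}
        if d.keep_quadratic:
            X["age_sq"] = X["age"] ** 2

    # --- step 1: single-level ---
    fit1 = glm.SingleLevelLogistic().fit(X, y)
    scores1 = metrics.model_scores(fit1, X)
    auc1 = metrics.auc_ci(scores1, y)
    model1 = {
        "auc": auc1.auc, "auc_ci": [auc1.ci_low, auc1.ci_high],
        "or_table": glm.or_table(fit1).to_dict(orient="records"),
        "loglik": fit1.loglik_,
    }

    # --- step 2: department random intercept ---
    if config.method == "ml":
        fit2 = mlm.RandomInterceptLogistic(method="ml").fit(X, y, groups)
        icc = metrics.icc_interval(
            variance_interval=fit2.dept_variance_interval_,
            point_variance=fit2.dept_variance_)
        dic2 = None
        loglik2 = fit2.loglik_
        dic1 = None
    elif config.method == "mcmc":
        fit2 = mlm.RandomInterceptLogistic(method="mcmc", mcmc=config.mcmc).fit(
            X, y, groups)
        icc = metrics.icc_interval(draws=fit2.draws_["sigma2"],
                                   point_variance=fit2.dept_variance_)
        dic2 = fit2.dic_
        loglik2 = None
        dic1 = mlm.fit_single_level_mcmc(X, y, config=config.mcmc).dic_
        model1["dic"] = dic1
    else:
        raise ValueError("method must be 'ml' or 'mcmc'")

    scores2 = metrics.model_scores(fit2, X, cluster=groups,
                                   include_random_effects=True)
    auc2 = metrics.auc_ci(scores2, y, include_random_effects=True)
    model2 = {
        "auc": auc2.auc, "auc_ci": [auc2.ci_low, auc2.ci_high],
        "or_table": glm.or_table(fit2).to_dict(orient="records"),
        "dept_variance": fit2.dept_variance_,
        "dept_variance_interval": list(fit2.dept_variance_interval_),
        "dic": dic2,
        "loglik": loglik2,
    }

    report = GCEReport(
        period=config.period_label,
        n_patients=cohort.n_patients,
        n_departments=cohort.n_departments,
        covariate_set=config.covariate_set,
        method=config.method,
        model1=model1,
        model2=model2,
        delta_auc=metrics.delta_auc(auc2, auc1),
        icc={
            "icc": metrics.icc_latent(fit2.dept_variance_).icc,
            "percent": metrics.icc_latent(fit2.dept_variance_).percent,
            "interval": list(icc.interval),
            "interval_mode": icc.interval_mode,
            "source_variance": fit2.dept_variance_,
        },
        age_linearity=age_decision,
        terms=list(fit2.params_.index),
    )

    if config.check_three_level:
        part = mlm.fit_three_level_empty(
            y, df["dept_id"], df["hospital_id"], config=config.mcmc)
        report.three_level = {
            "dept_variance": part.dept_variance,
            "hosp_variance": part.hosp_variance,
            "icc_dept": part.icc_dept,
            "icc_hosp": part.icc_hosp,
            "proceed_two_level": part.icc_hosp < config.three_level_icc_threshold,
        }
    if config.check_random_slope:
        if score is None:
            warnings.warn("random-slope check requires a risk score "
                          "(swedish covariate set); skipped", UserWarning)
        else:
            Xrs = df[["female", "age"]].astype(float).copy()
            Xrs["age"] = Xrs["age"] - Xrs["age"].mean()
            Xrs["rs_centered"] = score.rs - score.rs.mean()
            report.random_slope = mlm.random_slope_check(
                Xrs, y, groups, "rs_centered", config=config.mcmc)

    return report, fit2


def league_table(fit) -> pd.DataFrame:
    """Departments ranked by shrunken residual (log-odds vs the overall average).

    Columns ``rank, dept_id, n_patients, residual, se, ci_low, ci_high,
    overlaps_reference``; rank 1 is the lowest (best) residual.  The
    frame carries the fraction of departments whose CI excludes 0 in
    ``.attrs['fraction_outside_reference']``.
    """
    res = mlm.shrunken_residuals(fit)
    out = res.rename(columns={"cluster": "dept_id"}).sort_values(
        "residual", kind="mergesort").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out["overlaps_reference"] = (out["ci_low"] <= 0) & (out["ci_high"] >= 0)
    out.attrs["fraction_outside_reference"] = float(1 - out["overlaps_reference"].mean())
    return out[["rank", "dept_id", "n_patients", "residual", "se",
                "ci_low", "ci_high", "overlaps_reference"]]


def render_caterpillar(league: pd.DataFrame, path: str | Path,
                       annotation: str = "") -> Path:
    """Caterpillar plot of ranked department residuals with 95% CI whiskers.

    Writes both the image at ``path`` and a plot-data CSV next to it
    (same stem, ``.csv``); the CSV is the bit-stable artifact, the
    image is presentational.  ``annotation`` typically carries the
    report's ICC and AUC values.
    """
    if len(league) == 0:
        raise ValueError("empty league table")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    csv_path = path.with_suffix(".csv")
    league.to_csv(csv_path, index=False, float_format="%.6f")

    fig, ax = plt.subplots(figsize=(max(6, len(league) / 12), 4))
    ax.errorbar(league["rank"], league["residual"],
                yerr=[league["residual"] - league["ci_low"],
                      league["ci_high"] - league["residual"]],
                fmt="o", ms=2.5, lw=0.7, capsize=0, color="tab:blue",
                ecolor="0.6")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("department rank")
    ax.set_ylabel("shrunken residual (log-odds vs overall average)")
    if annotation:
        ax.set_title(annotation, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
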