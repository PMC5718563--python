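"""Synthetic register-like heart-failure cohorts.

Patient-level data with the nesting structure of a national clinical
register — patients within hospital departments within hospitals — are
generated from a random-intercept logistic model with known department
variance, so every downstream stage (single-level and multilevel fits,
ICC, AUC, league tables) can be exercised and validated against the
generative truth.

Two presets emulate published register descriptives:

* ``danish_like`` — an incident heart-failure audit cohort: ~4,000
  patients per audit year in ~40 departments across 32 hospitals,
  marginal one-year mortality ~13%, 32% female, median age ~71,
  department variance 0.115 on the logit scale.
* ``swedish_like`` — a first-hospitalisation cohort: ~12,000 patients
  per calendar year in ~450 departments across 71 hospitals, marginal
  mortality ~22%, 40% female, 18 binary comorbidity indicators for
  case-mix risk-score construction, department variance 0.05.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "CohortSpec",
    "Cohort",
    "preset_spec",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "calibrate_intercept",
    "PRESET_NAMES",
]

PRESET_NAMES = ("danish_like", "swedish_like")

_REQUIRED_COLUMNS = ["patient_id", "dept_id", "hospital_id", "outcome", "age", "female"]


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic register cohort.

    The outcome model is a random-intercept logistic regression:
    logit P(death) = intercept + log_or_age*(age - age_mean)
    + log_or_female*female + sum_k com_k*comorbidity_log_ors[k]
    + u_dept + u_hosp, with u_dept ~ N(0, dept_variance) and
    u_hosp ~ N(0, hosp_variance).  ``intercept`` is therefore the
    log-odds of death for a male patient of mean age with no recorded
    comorbidity in an average department.
    """

    n_patients: int
    n_departments: int
    n_hospitals: int
    dept_variance: float
    intercept: float
    hosp_variance: float = 0.0
    age_mean: float = 71.0
    age_sd: float = 9.0
    age_min: float | None = None
    age_max: float | None = None
    female_fraction: float = 0.35
    log_or_age: float = 0.0
    log_or_female: float = 0.0
    comorbidity_prevalences: tuple[float, ...] = ()
    comorbidity_log_ors: tuple[float, ...] = ()
    dept_size_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.comorbidity_prevalences = tuple(self.comorbidity_prevalences)
        self.comorbidity_log_ors = tuple(self.comorbidity_log_ors)
        self.validate()

    @property
    def n_comorbidities(self) -> int:
        return len(self.comorbidity_prevalences)

    def validate(self) -> None:
        if self.dept_variance < 0 or self.hosp_variance < 0:
            raise ValueError("variances must be non-negative")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must be a proportion in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.comorbidity_prevalences):
            raise ValueError("comorbidity prevalences must be proportions in [0, 1]")
        if len(self.comorbidity_prevalences) != len(self.comorbidity_log_ors):
            raise ValueError(
                "comorbidity_prevalences and comorbidity_log_ors must have equal length"
            )
        if not (self.n_departments >= self.n_hospitals >= 1):
            raise ValueError("need n_departments >= n_hospitals >= 1")
        if self.n_patients < self.n_departments:
            raise ValueError("need n_patients >= n_departments")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if self.dept_size_dispersion <= 0:
            raise ValueError("dept_size_dispersion must be positive")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["comorbidity_prevalences"] = list(self.comorbidity_prevalences)
        data["comorbidity_log_ors"] = list(self.comorbidity_log_ors)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class Cohort:
    """A patient table with department/hospital nesting.

    ``data`` has one row per patient with columns ``patient_id, dept_id,
    hospital_id, outcome, age, female`` and, when K comorbidity
    indicators are present, ``com_1 .. com_K``.  The optional
    ``true_linear_predictor`` column carries the generative log-odds for
    diagnostics and is dropped on CSV export.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def n_departments(self) -> int:
        return self.data["dept_id"].nunique()

    @property
    def n_hospitals(self) -> int:
        return self.data["hospital_id"].nunique()

    @property
    def comorbidity_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("com_")]

    @property
    def mortality(self) -> float:
        return float(self.data["outcome"].mean())

    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            raise ValueError("no records")
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        check_cols = _REQUIRED_COLUMNS + self.comorbidity_columns
        if df[check_cols].isna().any().any():
            bad = int(df[check_cols].isna().any(axis=1).idxmax())
            raise ValueError(f"missing value in required field at row {bad}")
        for col in ["outcome", "female"] + self.comorbidity_columns:
            bad = ~df[col].isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"column {col!r} must be binary 0/1; offending row {row} "
                    f"has value {df[col].iloc[row]!r}"
                )
        # each department must sit under exactly one hospital
        n_hosp_per_dept = df.groupby("dept_id")["hospital_id"].nunique()
        violators = n_hosp_per_dept[n_hosp_per_dept > 1]
        if len(violators):
            raise ValueError(
                f"department(s) {list(violators.index)} appear under multiple hospitals"
            )


def _danish_comorbidity_params() -> tuple[tuple[float, ...], tuple[float, ...]]:
    return (), ()


def _swedish_comorbidity_params() -> tuple[tuple[float, ...], tuple[float, ...]]:
    # 18 diagnosis-group indicators (cerebrovascular, arrhythmia,
    # hypertension, IHD, ... injury).  Prevalences and effects chosen in
    # the range typical of pre-admission comorbidity in elderly HF
    # cohorts (OR ~1.1-1.65) so that a case-mix risk score built from
    # them shows the familiar steep mortality gradient across deciles.
    prev = (0.25, 0.20, 0.35, 0.30, 0.12, 0.05, 0.10, 0.15, 0.20,
            0.15, 0.18, 0.08, 0.12, 0.04, 0.10, 0.06, 0.12, 0.10)
    logor = (0.35, 0.30, 0.15, 0.30, 0.10, 0.15, 0.40, 0.20, 0.30,
             0.20, 0.35, 0.30, 0.45, 0.50, 0.25, 0.20, 0.30, 0.25)
    return prev, logor


# Intercepts frozen from a one-off Monte-Carlo bisection (10^6 draws of
# the marginal mortality under each preset's full generative model); the
# marginal mean of a logistic random-intercept model has no closed form.
_DANISH_INTERCEPT = -2.1082
_SWEDISH_INTERCEPT = -1.9049


def preset_spec(name: str) -> CohortSpec:
    """Return the generative spec for a named register-like preset.

    ``danish_like``: 4,000 patients / 40 departments / 32 hospitals,
    marginal mortality ~0.13, department variance 0.115.
    ``swedish_like``: 12,000 patients / 450 departments / 71 hospitals,
    marginal mortality ~0.22, department variance 0.050, K=18
    comorbidity indicators.
    """
    if name == "danish_like":
        prev, logor = _danish_comorbidity_params()
        return CohortSpec(
            n_patients=4000,
            n_departments=40,
            n_hospitals=32,
            dept_variance=0.115,
            hosp_variance=0.0,
            intercept=_DANISH_INTERCEPT,
            age_mean=71.0,
            age_sd=9.0,
            age_min=18.0,
            age_max=None,
            female_fraction=0.32,
            log_or_age=float(np.log(1.08)),
            log_or_female=0.0,
            comorbidity_prevalences=prev,
            comorbidity_log_ors=logor,
        )
    if name == "swedish_like":
        prev, logor = _swedish_comorbidity_params()
        return CohortSpec(
            n_patients=12000,
            n_departments=450,
            n_hospitals=71,
            dept_variance=0.050,
            hosp_variance=0.0,
            intercept=_SWEDISH_INTERCEPT,
            age_mean=71.5,
            age_sd=9.0,
            age_min=45.0,
            age_max=80.0,
            female_fraction=0.40,
            log_or_age=float(np.log(1.04)),
            log_or_female=float(np.log(0.85)),
            comorbidity_prevalences=prev,
            comorbidity_log_ors=logor,
        )
    raise ValueError(
        f"unknown preset {name!r}; valid presets are {list(PRESET_NAMES)}"
    )


def _truncated_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                      lo: float | None, hi: float | None) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    lo_ = -np.inf if lo is None else lo
    hi_ = np.inf if hi is None else hi
    bad = (out < lo_) | (out > hi_)
    # redraw out-of-window ages; window always has substantial mass here
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo_) | (out > hi_)
    return out


def _department_sizes(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Unequal department sizes from a symmetric Dirichlet.

    Proportions are Dirichlet(dept_size_dispersion) and scaled to
    n_patients; rounding residue is assigned to the largest department,
    so some departments end up with few patients, as in real registers.
    """
    props = rng.dirichlet(np.full(spec.n_departments, spec.dept_size_dispersion))
    sizes = np.floor(props * spec.n_patients).astype(int)
    sizes[np.argmax(sizes)] += spec.n_patients - sizes.sum()
    return sizes


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Draw one cohort from the spec's random-intercept logistic model.

    Departments are assigned to hospitals (each hospital gets at least
    one), department and hospital intercepts are drawn from their normal
    distributions, covariates per patient, and the outcome is Bernoulli
    of the inverse-logit of the full linear predictor.  A single
    ``numpy`` generator stream derived from ``seed`` governs every
    draw, so identical (spec, seed) pairs give identical cohorts.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    # hospitals: first cover every hospital once, then assign the rest at random
    hosp_of_dept = np.concatenate([
        np.arange(spec.n_hospitals),
        rng.integers(0, spec.n_hospitals, size=spec.n_departments - spec.n_hospitals),
    ])
    rng.shuffle(hosp_of_dept)

    sizes = _department_sizes(rng, spec)
    dept_of_patient = np.repeat(np.arange(spec.n_departments), sizes)

    u_dept = rng.normal(0.0, np.sqrt(spec.dept_variance), size=spec.n_departments)
    u_hosp = rng.normal(0.0, np.sqrt(spec.hosp_variance), size=spec.n_hospitals)

    n = spec.n_patients
    age = _truncated_normal(rng, n, spec.age_mean, spec.age_sd, spec.age_min, spec.age_max)
    female = (rng.random(n) < spec.female_fraction).astype(int)

    lp = (
        spec.intercept
        + spec.log_or_age * (age - spec.age_mean)
        + spec.log_or_female * female
        + u_dept[dept_of_patient]
        + u_hosp[hosp_of_dept[dept_of_patient]]
    )
    com = {}
    for k, (p, b) in enumerate(zip(spec.comorbidity_prevalences, spec.comorbidity_log_ors), 1):
        x = (rng.random(n) < p).astype(int)
        com[f"com_{k}"] = x
        lp = lp + b * x

    outcome = (rng.random(n) < expit(lp)).astype(int)

    dept_width = max(2, len(str(spec.n_departments)))
    hosp_width = max(2, len(str(spec.n_hospitals)))
    df = pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "dept_id": [f"D{j + 1:0{dept_width}d}" for j in dept_of_patient],
        "hospital_id": [f"H{h + 1:0{hosp_width}d}" for h in hosp_of_dept[dept_of_patient]],
        "outcome": outcome,
        "age": np.round(age, 2),
        "female": female,
        **com,
        "true_linear_predictor": lp,
    })
    return Cohort(df)


def calibrate_intercept(spec: CohortSpec, target_mortality: float,
                        n_mc: int = 1_000_000, seed: int = 0,
                        tol: float = 1e-4) -> float:
    """Bisection for the intercept giving a target marginal mortality.

    The marginal mean of a logistic random-intercept model has no closed
    form, so the marginal probability is evaluated by Monte Carlo
    (``n_mc`` draws of covariates and random effects, common random
    numbers across bisection steps) and the intercept is bisected until
    the target is met within ``tol``.
    """
    rng = np.random.default_rng(seed)
    n = n_mc
    age = _truncated_normal(rng, n, spec.age_mean, spec.age_sd, spec.age_min, spec.age_max)
    female = (rng.random(n) < spec.female_fraction).astype(int)
    re = rng.normal(0.0, np.sqrt(spec.dept_variance + spec.hosp_variance), size=n)
    base = spec.log_or_age * (age - spec.age_mean) + spec.log_or_female * female + re
    for p, b in zip(spec.comorbidity_prevalences, spec.comorbidity_log_ors):
        base = base + b * (rng.random(n) < p)

    def marginal(b0: float) -> float:
        return float(expit(b0 + base).mean())

    lo, hi = -10.0, 5.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if marginal(mid) < target_mortality:
            lo = mid
        else:
            hi = mid
        if abs(marginal(0.5 * (lo + hi)) - target_mortality) < tol:
            break
    return 0.5 * (lo + hi)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV (schema: patient_id,dept_id,hospital_id,outcome,age,female,com_1..com_K)."""
    cols = _REQUIRED_COLUMNS + cohort.comorbidity_columns
    cohort.data[cols].to_csv(path, index=False)


def read_cohort(path: str | Path | io.TextIOBase) -> Cohort:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "dept_id": str, "hospital_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError("no records") from None
    if len(df) == 0:
        raise ValueError("no records")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed header: missing column(s) {missing}")
    return Cohort(df)
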