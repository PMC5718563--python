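"""General-contextual-effect measures: latent-method ICC and AUC change.

Two complementary quantities summarise how much the hospital department
matters for a patient's outcome over and above patient characteristics:

* the intra-class correlation coefficient by the latent-response
  method, ICC = sigma^2 / (sigma^2 + pi^2/3) — the correlation in the
  latent propensity of the outcome between two patients from the same
  department;
* the gain in the area under the ROC curve when the department random
  effects are added to the prediction equation (delta-AUC).

Both near zero means departments behave like random samples of the
national patient population — performance is homogeneous and league
tables carry little signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit  # noqa: F401  (re-exported convenience)
from scipy.stats import rankdata

__all__ = [
    "IccResult",
    "AucResult",
    "LOGISTIC_RESIDUAL_VARIANCE",
    "icc_latent",
    "icc_interval",
    "auc_mannwhitney",
    "auc_ci",
    "model_scores",
    "delta_auc",
    "format_icc_percent",
]

#: variance of the standard logistic distribution, pi^2/3
LOGISTIC_RESIDUAL_VARIANCE = np.pi ** 2 / 3


@dataclass
class IccResult:
    """Latent-method intraclass correlation, as a proportion."""

    icc: float
    source_variance: float
    interval: tuple[float, float] | None = None
    interval_mode: str | None = None  # "endpoint_transform" or "posterior_draws"

    @property
    def percent(self) -> float:
        """ICC as a percentage rounded to one decimal (reporting convention)."""
        return round(100.0 * self.icc, 1)

    def render(self, strip_trailing_zero: bool = False) -> str:
        def fmt(v: float) -> str:
            s = f"{100.0 * v:.1f}"
            if strip_trailing_zero and s.endswith(".0"):
                s = s[:-2]
            return s

        if self.interval is None:
            return f"{fmt(self.icc)}%"
        lo, hi = self.interval
        return f"{fmt(self.icc)}% ({fmt(lo)}–{fmt(hi)})"


@dataclass
class AucResult:
    """Area under the ROC curve with optional DeLong interval."""

    auc: float
    n_cases: int
    n_controls: int
    ci_low: float | None = None
    ci_high: float | None = None
    se: float | None = None
    includes_random_effects: bool = False
    degenerate_ci: bool = False


def icc_latent(sigma2: float) -> IccResult:
    """ICC by the latent-variable method: sigma^2 / (sigma^2 + pi^2/3)."""
    if sigma2 < 0:
        raise ValueError("variance must be non-negative")
    return IccResult(
        icc=float(sigma2 / (sigma2 + LOGISTIC_RESIDUAL_VARIANCE)),
        source_variance=float(sigma2),
    )


def icc_interval(variance_interval=None, draws=None,
                 point_variance: float | None = None) -> IccResult:
    """ICC with a 95% interval, from a variance interval or posterior draws.

    Endpoint mode maps the variance interval through the (monotone)
    latent-method formula; draw mode applies the formula to each
    posterior draw and takes 2.5/97.5 percentiles (in which case the
    point estimate is the posterior median of the ICC, a convention
    that can differ from ICC-of-the-median-variance in the last
    printed decimal).
    """
    if (variance_interval is None) == (draws is None):
        raise ValueError("give exactly one of variance_interval or draws")
    if draws is not None:
        draws = np.asarray(draws, dtype=float)
        if (draws < 0).any():
            raise ValueError("variance draws must be non-negative")
        icc_draws = draws / (draws + LOGISTIC_RESIDUAL_VARIANCE)
        lo, hi = np.percentile(icc_draws, [2.5, 97.5])
        point = float(np.median(icc_draws)) if point_variance is None \
            else icc_latent(point_variance).icc
        src = float(np.median(draws)) if point_variance is None else point_variance
        return IccResult(icc=point, source_variance=src,
                         interval=(float(lo), float(hi)),
                         interval_mode="posterior_draws")
    lo_v, hi_v = variance_interval
    if lo_v < 0 or hi_v < 0:
        raise ValueError("interval endpoints must be non-negative")
    if lo_v > hi_v:
        raise ValueError("interval endpoints must be ordered (low <= high)")
    point = icc_latent(point_variance if point_variance is not None
                       else 0.5 * (lo_v + hi_v))
    return IccResult(
        icc=point.icc,
        source_variance=point.source_variance,
        interval=(icc_latent(lo_v).icc, icc_latent(hi_v).icc),
        interval_mode="endpoint_transform",
    )


def _split_classes(scores, outcomes):
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    if not np.isin(outcomes, [0, 1]).all():
        raise ValueError("outcomes must be binary 0/1")
    if outcomes.min() == outcomes.max():
        raise ValueError("both outcome classes must be present")
    return scores, outcomes.astype(bool)


def auc_mannwhitney(scores, outcomes,
                    include_random_effects: bool = False) -> AucResult:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2).

    Rank-based, O(n log n): AUC = (R_cases - n1(n1+1)/2) / (n1*n0)
    with midranks handling ties.
    """
    scores, case = _split_classes(scores, outcomes)
    n1, n0 = int(case.sum()), int((~case).sum())
    ranks = rankdata(scores)
    auc = (ranks[case].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return AucResult(auc=float(auc), n_cases=n1, n_controls=n0,
                     includes_random_effects=include_random_effects)


def auc_ci(scores, outcomes, include_random_effects: bool = False) -> AucResult:
    """AUC with a DeLong 95% confidence interval (truncated to [0, 1]).

    Uses the midrank formulation of the DeLong placement values, which
    is exact in the presence of ties.
    """
    scores, case = _split_classes(scores, outcomes)
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 cases and 2 controls for a CI")
    x, yctl = scores[case], scores[~case]
    all_ranks = rankdata(scores)
    rx = rankdata(x)
    ry = rankdata(yctl)
    # placement values (Sun & Xu midrank formulation)
    v10 = (all_ranks[case] - rx) / n0          # P(score_control < case_i)
    v01 = 1.0 - (all_ranks[~case] - ry) / n1   # P(score_case > control_j)... complement
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    se = float(np.sqrt(s10 / n1 + s01 / n0))
    degenerate = se == 0.0
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return AucResult(auc=auc, n_cases=n1, n_controls=n0, ci_low=lo, ci_high=hi,
                     se=se, includes_random_effects=include_random_effects,
                     degenerate_ci=degenerate)


def model_scores(fit, X, cluster=None, include_random_effects: bool = False) -> np.ndarray:
    """Predicted log-odds used as the ROC discriminator.

    With ``include_random_effects`` the per-department shrunken
    residual is added to the fixed-effect linear predictor — the
    multilevel prediction equation whose AUC gain over the single-level
    one measures the general contextual effect.
    """
    if include_random_effects:
        if not hasattr(fit, "residuals_"):
            raise ValueError("include_random_effects requires a multilevel fit")
        return fit.decision_function(X, groups=cluster, include_random_effects=True)
    return fit.decision_function(X)


def delta_auc(auc_with: AucResult, auc_without: AucResult) -> float:
    """AUC(with random effects) - AUC(without), to 3 decimals.

    Both AUCs must come from the same outcome vector (checked via case
    and control counts).
    """
    if (auc_with.n_cases, auc_with.n_controls) != \
            (auc_without.n_cases, auc_without.n_controls):
        raise ValueError("AUCs computed on different outcome vectors "
                         "(case/control counts differ)")
    return round(auc_with.auc - auc_without.auc, 3)


def format_icc_percent(sigma2: float, strip_trailing_zero: bool = False) -> str:
    """One-call rendering of a variance to the ICC percentage string."""
    return icc_latent(sigma2).render(strip_trailing_zero=strip_trailing_zero)
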