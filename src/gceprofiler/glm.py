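"""Single-level binary logistic regression (step 1 of the two-step analysis).

The estimator is a plain maximum-likelihood logistic regression fitted
by iteratively reweighted least squares with step-halving, exposing the
pieces the profiling pipeline needs: coefficient covariance for Wald
odds-ratio tables, the log-likelihood, and linear-predictor scores for
ROC analysis.  It deliberately reports — rather than penalises —
separation, and provides the quadratic-age linearity check used when
deciding whether age can enter the case-mix models linearly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SingleLevelLogistic",
    "fit_logistic",
    "predict_logit",
    "or_table",
    "check_quadratic_age",
    "SeparationWarning",
]


class SeparationWarning(UserWarning):
    """Raised when coefficients diverge (complete or quasi-complete separation)."""


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        if len(set(names)) != len(names):
            raise ValueError("design matrix column names must be unique")
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{j}" for j in range(arr.shape[1])]
    if np.isnan(arr).any():
        raise ValueError("design matrix contains missing values")
    return arr, names


class SingleLevelLogistic:
    """Maximum-likelihood logistic regression via IRLS.

    Parameters
    ----------
    add_intercept : bool
        Prepend an intercept column (named ``intercept``).
    tol_loglik : float
        Convergence when the relative log-likelihood change drops below
        this.
    tol_grad : float
        Alternative convergence: max-norm of the score below this.
    max_iter : int
        IRLS iteration cap.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : pd.Series of coefficients (log-odds scale)
    cov_params_ : pd.DataFrame, inverse observed information
    bse_ : pd.Series of standard errors
    loglik_ : float
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, add_intercept: bool = True, tol_loglik: float = 1e-10,
                 tol_grad: float = 1e-8, max_iter: int = 200):
        self.add_intercept = add_intercept
        self.tol_loglik = tol_loglik
        self.tol_grad = tol_grad
        self.max_iter = max_iter

    # minimal get/set_params so the class composes with sklearn utilities
    def get_params(self, deep: bool = True) -> dict:
        return {
            "add_intercept": self.add_intercept,
            "tol_loglik": self.tol_loglik,
            "tol_grad": self.tol_grad,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "SingleLevelLogistic":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _prepare(self, X) -> tuple[np.ndarray, list[str]]:
        arr, names = _as_design(X)
        if self.add_intercept:
            if "intercept" in names:
                raise ValueError("design already has an 'intercept' column")
            arr = np.column_stack([np.ones(len(arr)), arr])
            names = ["intercept"] + names
        return arr, names

    @staticmethod
    def _loglik(Xb: np.ndarray, y: np.ndarray) -> float:
        # numerically stable: -log(1+exp(-(2y-1) Xb))
        return float(-np.logaddexp(0.0, -(2 * y - 1) * Xb).sum())

    def fit(self, X, y) -> "SingleLevelLogistic":
        Xmat, names = self._prepare(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(Xmat):
            raise ValueError("X and y lengths differ")
        if not np.isin(y, [0, 1]).all():
            raise ValueError("outcome must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome has a single class")
        if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
            raise ValueError("design matrix is rank deficient")

        beta = np.zeros(Xmat.shape[1])
        ll = self._loglik(Xmat @ beta, y)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = Xmat @ beta
            p = expit(eta)
            w = p * (1 - p)
            grad = Xmat.T @ (y - p)
            H = (Xmat * w[:, None]).T @ Xmat
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step-halving: the log-likelihood never decreases
            scale = 1.0
            for _ in range(40):
                cand = beta + scale * step
                ll_new = self._loglik(Xmat @ cand, y)
                if ll_new >= ll:
                    break
                scale *= 0.5
            beta = beta + scale * step
            rel = abs(ll_new - ll) / (abs(ll) + 1e-300)
            ll = ll_new
            if rel < self.tol_loglik or np.max(np.abs(grad)) < self.tol_grad:
                converged = True
                break

        grad = Xmat.T @ (y - expit(Xmat @ beta))
        if np.max(np.abs(beta)) > 15:
            # coefficients of this magnitude (OR > 3x10^6) only arise when
            # the likelihood has no interior maximum
            converged = False
            warnings.warn(
                "coefficients diverging (|beta|max "
                f"{np.max(np.abs(beta)):.1f}, gradient max-norm "
                f"{np.max(np.abs(grad)):.2e}): complete or quasi-complete "
                "separation suspected; fit flagged non-converged",
                SeparationWarning,
            )

        p = expit(Xmat @ beta)
        H = (Xmat * (p * (1 - p))[:, None]).T @ Xmat
        cov = np.linalg.pinv(H)

        self.feature_names_in_ = names
        self.params_ = pd.Series(beta, index=names)
        self.cov_params_ = pd.DataFrame(cov, index=names, columns=names)
        self.bse_ = pd.Series(np.sqrt(np.diag(cov)), index=names)
        self.loglik_ = ll
        self.converged_ = converged
        self.n_iter_ = it
        self.n_obs_ = len(y)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Linear predictor X beta (log-odds), one value per row."""
        Xmat, names = self._prepare(X)
        if names != self.feature_names_in_:
            raise ValueError(
                f"column mismatch: fitted on {self.feature_names_in_}, got {names}"
            )
        return Xmat @ self.params_.to_numpy()

    def predict_proba(self, X) -> np.ndarray:
        return expit(self.decision_function(X))


def fit_logistic(X, y, **kwargs) -> SingleLevelLogistic:
    """Fit a single-level logistic regression (thin estimator wrapper)."""
    return SingleLevelLogistic(**kwargs).fit(X, y)


def predict_logit(fit: SingleLevelLogistic, X) -> np.ndarray:
    """Predicted log-odds X beta from a fitted model."""
    return fit.decision_function(X)


def or_table(fit, exclude: tuple[str, ...] = ("intercept",)) -> pd.DataFrame:
    """Odds ratios with Wald 95% CIs, one row per coefficient.

    Columns ``term, or, ci_low, ci_high`` on the OR scale, plus the raw
    log-odds ``beta`` and ``se``.  Works for both single-level and
    multilevel fits (anything exposing ``params_``/``bse_``/``converged_``).
    """
    if not getattr(fit, "converged_", False):
        raise ValueError("fit did not converge; no odds-ratio table")
    z = norm.ppf(0.975)
    rows = []
    for term in fit.params_.index:
        if term in exclude:
            continue
        b = fit.params_[term]
        se = fit.bse_[term]
        rows.append({
            "term": term,
            "or": np.exp(b),
            "ci_low": np.exp(b - z * se),
            "ci_high": np.exp(b + z * se),
            "beta": b,
            "se": se,
        })
    return pd.DataFrame(rows)


def format_or_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render an OR table to two decimals, e.g. ``1.08 (1.07-1.09)``."""
    out = table.copy()
    out["display"] = [
        f"{r['or']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})"
        for _, r in table.iterrows()
    ]
    return out[["term", "display"]]


@dataclass
class QuadraticAgeDecision:
    keep_quadratic: bool
    wald_p: float
    quadratic_coef: float
    linear_fit: SingleLevelLogistic
    quadratic_fit: SingleLevelLogistic


def check_quadratic_age(X: pd.DataFrame, y, age_column: str = "age",
                        alpha: float = 0.05) -> QuadraticAgeDecision:
    """Wald test for curvature in the age effect.

    Refits the model with centred age plus centred-age-squared and keeps
    the quadratic term only if its Wald p-value is below ``alpha``; in
    register cohorts the association is typically linear and the term is
    dropped.
    """
    if age_column not in X.columns:
        raise ValueError(f"age column {age_column!r} not in design")
    age = X[age_column].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age column is constant (rank deficiency)")
    centered = age - age.mean()
    Xq = X.copy()
    Xq[age_column] = centered
    Xq[f"{age_column}_sq"] = centered ** 2
    Xl = X.copy()
    Xl[age_column] = centered

    linear = SingleLevelLogistic().fit(Xl, y)
    quad = SingleLevelLogistic().fit(Xq, y)
    term = f"{age_column}_sq"
    zstat = quad.params_[term] / quad.bse_[term]
    p = 2 * norm.sf(abs(zstat))
    return QuadraticAgeDecision(
        keep_quadratic=bool(p < alpha),
        wald_p=float(p),
        quadratic_coef=float(quad.params_[term]),
        linear_fit=linear,
        quadratic_fit=quad,
    )
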