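"""Multilevel (random-intercept) logistic regression for nested patients.

Step 2 of the two-step profiling analysis: patients nested in hospital
departments, with a department-level normal random intercept on the
logit scale.  Two estimation paths are provided:

* ``ml`` — marginal maximum likelihood where each department's
  likelihood contribution, an intractable integral over its random
  intercept, is evaluated by adaptive Gauss-Hermite quadrature (mode
  and curvature adapted per cluster).
* ``mcmc`` — Metropolis-within-Gibbs: random-walk Metropolis updates
  for the fixed effects and the cluster intercepts (scales adapted
  during burn-in towards 0.44 acceptance), and a conjugate
  inverse-gamma draw for the variance.  The variance is summarised as
  the posterior median with a 95% credible interval, and the deviance
  information criterion (DIC) is computed from the conditional
  deviance.

Shrunken (empirical-Bayes / posterior) department residuals with
comparative standard errors feed the league tables; the three-level
empty model and the random-slope check support the exploratory choices
around the main two-level specification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import invwishart

from .glm import SingleLevelLogistic, _as_design

__all__ = [
    "RandomInterceptLogistic",
    "McmcConfig",
    "VariancePartition3",
    "fit_random_intercept_ml",
    "fit_random_intercept_mcmc",
    "fit_single_level_mcmc",
    "fit_three_level_empty",
    "random_slope_check",
    "dic",
    "shrunken_residuals",
    "marginal_loglik_per_cluster",
]

_LOGISTIC_VAR = np.pi ** 2 / 3


def _row_loglik(lp: np.ndarray, y: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -(2.0 * y - 1.0) * lp)


def _encode_groups(groups) -> tuple[np.ndarray, np.ndarray]:
    codes, labels = pd.factorize(np.asarray(groups), sort=True)
    if (codes < 0).any():
        raise ValueError("missing cluster label")
    return codes, np.asarray(labels)


@dataclass
class McmcConfig:
    """Chain settings and priors for the Metropolis-within-Gibbs sampler.

    Defaults are long (50,000 kept iterations, thinned by 10, after
    5,000 burn-in) because variance components near the boundary mix
    slowly.  ``variance_prior`` is ``inverse_gamma`` (shape/scale
    0.001, a conventional vague choice) or ``uniform_sd`` (flat on the
    standard deviation), offered because the inverse-gamma is known to
    be influential when the variance is near zero.
    """

    n_burnin: int = 5000
    n_iter: int = 50000
    thin: int = 10
    seed: int = 0
    prior_fixed_sd: float = 1000.0
    prior_variance_shape: float = 0.001
    prior_variance_scale: float = 0.001
    variance_prior: str = "inverse_gamma"

    def validate(self) -> None:
        if min(self.n_burnin, self.n_iter, self.thin) <= 0:
            raise ValueError("chain counts must be positive")
        if self.prior_fixed_sd <= 0 or self.prior_variance_shape <= 0 \
                or self.prior_variance_scale <= 0:
            raise ValueError("priors must be proper (positive hyperparameters)")
        if self.variance_prior not in ("inverse_gamma", "uniform_sd"):
            raise ValueError("variance_prior must be 'inverse_gamma' or 'uniform_sd'")


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite machinery
# ---------------------------------------------------------------------------

def _cluster_modes(beta, sigma2, Xmat, y, codes, J, start=None):
    """Vectorised Newton for the per-cluster posterior modes of u."""
    Xb = Xmat @ beta
    m = np.zeros(J) if start is None else start.copy()
    for _ in range(100):
        p = expit(Xb + m[codes])
        g = np.bincount(codes, weights=y - p, minlength=J) - m / sigma2
        h = -np.bincount(codes, weights=p * (1 - p), minlength=J) - 1.0 / sigma2
        step = -g / h
        np.clip(step, -4.0, 4.0, out=step)
        m += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return m, Xb


def marginal_loglik_per_cluster(X, y, groups, beta, sigma2, n_quad: int = 15,
                                add_intercept: bool = True,
                                mode_start: np.ndarray | None = None) -> np.ndarray:
    """Per-cluster marginal log-likelihood of a random-intercept logistic model.

    Integrates the conditional likelihood against the N(0, sigma2)
    random-intercept density by adaptive Gauss-Hermite quadrature with
    ``n_quad`` nodes centred and scaled at each cluster's posterior
    mode and curvature.
    """
    Xmat, _ = _as_design(X)
    if add_intercept:
        Xmat = np.column_stack([np.ones(len(Xmat)), Xmat])
    y = np.asarray(y, dtype=float).ravel()
    codes, labels = _encode_groups(groups)
    return _aghq_loglik(np.asarray(beta, float), float(sigma2), Xmat, y, codes,
                        len(labels), n_quad, mode_start)[0]


def _aghq_loglik(beta, sigma2, Xmat, y, codes, J, n_quad, mode_start=None):
    """Returns (per-cluster loglik array, modes) by adaptive GH quadrature."""
    if sigma2 < 1e-12:
        ll = np.bincount(codes, weights=_row_loglik(Xmat @ beta, y), minlength=J)
        return ll, np.zeros(J)
    m, Xb = _cluster_modes(beta, sigma2, Xmat, y, codes, J, start=mode_start)
    p = expit(Xb + m[codes])
    curv = np.bincount(codes, weights=p * (1 - p), minlength=J) + 1.0 / sigma2
    s = 1.0 / np.sqrt(curv)  # per-cluster adaptive scale

    z, w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(w)
    # h_j(u) = sum_i ll_i(u) + log phi(u; 0, sigma2)
    terms = np.empty((n_quad, J))
    for k in range(n_quad):
        u_k = m + np.sqrt(2.0) * s * z[k]
        rows = _row_loglik(Xb + u_k[codes], y)
        h = (np.bincount(codes, weights=rows, minlength=J)
             - 0.5 * np.log(2 * np.pi * sigma2) - u_k ** 2 / (2 * sigma2))
        terms[k] = logw[k] + z[k] ** 2 + h
    ll = 0.5 * np.log(2.0) + np.log(s) + logsumexp(terms, axis=0)
    return ll, m


def _eb_residuals(beta, sigma2, Xmat, y, codes, J, n_quad):
    """Posterior mean and SD of each cluster intercept by the same quadrature."""
    if sigma2 < 1e-12:
        return np.zeros(J), np.zeros(J)
    m, Xb = _cluster_modes(beta, sigma2, Xmat, y, codes, J)
    p = expit(Xb + m[codes])
    curv = np.bincount(codes, weights=p * (1 - p), minlength=J) + 1.0 / sigma2
    s = 1.0 / np.sqrt(curv)
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(w)
    logwt = np.empty((n_quad, J))
    nodes = np.empty((n_quad, J))
    for k in range(n_quad):
        u_k = m + np.sqrt(2.0) * s * z[k]
        rows = _row_loglik(Xb + u_k[codes], y)
        h = (np.bincount(codes, weights=rows, minlength=J)
             - u_k ** 2 / (2 * sigma2))
        logwt[k] = logw[k] + z[k] ** 2 + h
        nodes[k] = u_k
    logwt -= logsumexp(logwt, axis=0, keepdims=True)
    wt = np.exp(logwt)
    mean = (wt * nodes).sum(axis=0)
    var = (wt * (nodes - mean) ** 2).sum(axis=0)
    return mean, np.sqrt(var)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class RandomInterceptLogistic:
    """Two-level logistic regression with a cluster random intercept.

    Parameters
    ----------
    method : {"ml", "mcmc"}
        Adaptive-quadrature maximum likelihood, or Metropolis-within-
        Gibbs MCMC (started, when possible, from the ML fit).
    n_quad : int
        Gauss-Hermite nodes per cluster for the ML path; doubled
        automatically if the log-likelihood at the optimum moves by
        more than 1e-4 when re-evaluated with twice the nodes.
    add_intercept : bool
        Prepend an intercept column.
    tol : float
        Relative log-likelihood convergence tolerance (ML path).
    mcmc : McmcConfig, optional
        Chain settings for the MCMC path.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_, bse_ : fixed effects and their SEs (posterior mean/SD for MCMC)
    dept_variance_ : cluster variance point estimate (ML) / posterior median (MCMC)
    dept_variance_interval_ : 95% Wald-on-log-variance (ML) or credible interval
    residuals_ : DataFrame of shrunken residuals per cluster
    loglik_ : marginal log-likelihood (ML path)
    dic_ : deviance information criterion (MCMC path)
    draws_ : dict of retained posterior draws (MCMC path)
    diagnostics_ : dict of fitting metadata
    """

    def __init__(self, method: str = "ml", n_quad: int = 15,
                 add_intercept: bool = True, tol: float = 1e-8,
                 mcmc: McmcConfig | None = None):
        self.method = method
        self.n_quad = n_quad
        self.add_intercept = add_intercept
        self.tol = tol
        self.mcmc = mcmc

    def get_params(self, deep: bool = True) -> dict:
        return {"method": self.method, "n_quad": self.n_quad,
                "add_intercept": self.add_intercept, "tol": self.tol,
                "mcmc": self.mcmc}

    def set_params(self, **params) -> "RandomInterceptLogistic":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- shared preparation -------------------------------------------------
    def _prepare(self, X, y, groups):
        Xmat, names = _as_design(X)
        if self.add_intercept:
            if "intercept" in names:
                raise ValueError("design already has an 'intercept' column")
            Xmat = np.column_stack([np.ones(len(Xmat)), Xmat])
            names = ["intercept"] + names
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(Xmat) or len(np.asarray(groups)) != len(y):
            raise ValueError("X, y and groups lengths differ")
        if y.min() == y.max():
            raise ValueError("outcome has a single class")
        codes, labels = _encode_groups(groups)
        if len(labels) < 2:
            raise ValueError("need at least 2 clusters for a multilevel model")
        return Xmat, names, y, codes, labels

    def fit(self, X, y, groups, start: "RandomInterceptLogistic | None" = None):
        if self.method == "ml":
            return self._fit_ml(X, y, groups)
        if self.method == "mcmc":
            return self._fit_mcmc(X, y, groups, start=start)
        raise ValueError("method must be 'ml' or 'mcmc'")

    # -- ML path ------------------------------------------------------------
    def _fit_ml(self, X, y, groups):
        Xmat, names, yv, codes, labels = self._prepare(X, y, groups)
        J, p = len(labels), Xmat.shape[1]

        sl = SingleLevelLogistic(add_intercept=False).fit(
            pd.DataFrame(Xmat, columns=names), yv)
        theta0 = np.append(sl.params_.to_numpy(), np.log(0.2))

        mode_cache = {"m": None}

        def make_nll(n_quad):
            def nll(theta):
                beta, lv = theta[:p], theta[p]
                sigma2 = np.exp(lv)
                ll, m = _aghq_loglik(beta, sigma2, Xmat, yv, codes, J, n_quad,
                                     mode_start=mode_cache["m"])
                mode_cache["m"] = m
                return -ll.sum()
            return nll

        n_quad = self.n_quad
        while True:
            nll = make_nll(n_quad)
            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B",
                bounds=[(None, None)] * p + [(-25.0, 5.0)],
                options={"ftol": self.tol, "gtol": 1e-7, "maxiter": 500})
            # node-count check: double nodes if the loglik is not stable
            if n_quad >= 4 * self.n_quad:
                break
            if abs(make_nll(2 * n_quad)(res.x) - res.fun) <= 1e-4:
                break
            n_quad *= 2
            theta0 = res.x

        theta = res.x
        beta, lv = theta[:p], theta[p]
        sigma2 = float(np.exp(lv))
        # the profile in log-variance flattens below ~1e-5, so estimates
        # stalling there are boundary solutions; report them as 0
        boundary = sigma2 < 1e-5
        if boundary:
            sigma2 = 0.0

        hess = _numerical_hessian(make_nll(n_quad), theta)
        cov = _safe_inv(hess)
        bse = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
        se_lv = float(np.sqrt(max(cov[p, p], 0.0)))
        if boundary or not np.isfinite(se_lv) or se_lv == 0:
            interval = (0.0, 0.0) if boundary else (sigma2, sigma2)
        else:
            interval = (sigma2 * np.exp(-1.96 * se_lv), sigma2 * np.exp(1.96 * se_lv))

        if boundary:
            eb_mean, eb_sd = np.zeros(J), np.zeros(J)
        else:
            eb_mean, eb_sd = _eb_residuals(beta, sigma2, Xmat, yv, codes, J, n_quad)
        self.residuals_ = _residual_frame(labels, eb_mean, eb_sd, codes)
        self.boundary_ = boundary
        if boundary:
            warnings.warn("cluster variance estimated at the boundary (~0); "
                          "all shrunken residuals are 0", UserWarning)

        self.feature_names_in_ = names
        self.params_ = pd.Series(beta, index=names)
        self.bse_ = pd.Series(bse, index=names)
        self.cov_params_ = pd.DataFrame(cov[:p, :p], index=names, columns=names)
        self.dept_variance_ = sigma2
        self.dept_variance_interval_ = interval
        self.loglik_ = float(-res.fun)
        self.dic_ = None
        self.draws_ = None
        self.converged_ = bool(res.success)
        self.method_ = "ml_quadrature"
        self.n_obs_ = len(yv)
        self.cluster_labels_ = labels
        self.diagnostics_ = {"n_quad": n_quad, "n_iter": int(res.nit),
                             "optimizer_message": str(res.message)}
        if not res.success:
            raise RuntimeError(
                f"quadrature ML did not converge: {res.message}; "
                f"trace: nit={res.nit}, fun={res.fun:.6f}")
        return self

    # -- MCMC path ----------------------------------------------------------
    def _fit_mcmc(self, X, y, groups, start=None):
        cfg = self.mcmc or McmcConfig()
        cfg.validate()
        Xmat, names, yv, codes, labels = self._prepare(X, y, groups)
        J, p = len(labels), Xmat.shape[1]
        rng = np.random.default_rng(cfg.seed)

        if start is not None and getattr(start, "params_", None) is not None:
            beta = start.params_.reindex(names).to_numpy(dtype=float)
            sigma2 = max(float(start.dept_variance_), 1e-3)
            u = start.residuals_["residual"].to_numpy(dtype=float).copy()
        else:
            try:
                ml = RandomInterceptLogistic(
                    method="ml", n_quad=self.n_quad,
                    add_intercept=False).fit(
                        pd.DataFrame(Xmat, columns=names), yv, groups)
                beta = ml.params_.to_numpy().copy()
                sigma2 = max(ml.dept_variance_, 1e-3)
                u = ml.residuals_["residual"].to_numpy().copy()
            except Exception:
                sl = SingleLevelLogistic(add_intercept=False).fit(
                    pd.DataFrame(Xmat, columns=names), yv)
                beta, sigma2, u = sl.params_.to_numpy().copy(), 0.1, np.zeros(J)

        out = _gibbs_random_intercept(Xmat, yv, codes, J, beta, sigma2, u,
                                      cfg, rng)
        self._store_mcmc(out, names, labels, codes, cfg)
        return self

    def _store_mcmc(self, out, names, labels, codes, cfg):
        beta_d, s2_d, u_d, dev_d = out["beta"], out["sigma2"], out["u"], out["deviance"]
        self.feature_names_in_ = names
        self.params_ = pd.Series(beta_d.mean(axis=0), index=names)
        self.bse_ = pd.Series(beta_d.std(axis=0, ddof=1), index=names)
        self.dept_variance_ = float(np.median(s2_d))
        self.dept_variance_mean_ = float(s2_d.mean())
        self.dept_variance_interval_ = tuple(np.percentile(s2_d, [2.5, 97.5]))
        u_mean, u_sd = u_d.mean(axis=0), u_d.std(axis=0, ddof=1)
        self.residuals_ = _residual_frame(labels, u_mean, u_sd, codes)
        self.loglik_ = None
        self.draws_ = out
        self.dic_ = dic(self)["dic"]
        self.boundary_ = False
        self.converged_ = True
        self.method_ = "mcmc"
        self.n_obs_ = len(codes)
        self.cluster_labels_ = labels
        rhat = _split_rhat(s2_d)
        self.diagnostics_ = {"config": cfg, "sigma2_split_rhat": rhat,
                             "acceptance": out["acceptance"]}
        if rhat > 1.1:
            warnings.warn(
                f"variance chain may not have mixed (split-Rhat {rhat:.3f} > 1.1)",
                UserWarning)
            self.diagnostics_["mixing_warning"] = True

    # -- prediction ---------------------------------------------------------
    def decision_function(self, X, groups=None,
                          include_random_effects: bool = False) -> np.ndarray:
        """Fixed-effect log-odds X beta, plus the cluster residual if asked."""
        Xmat, names = _as_design(X)
        if self.add_intercept:
            Xmat = np.column_stack([np.ones(len(Xmat)), Xmat])
            names = ["intercept"] + names
        if names != self.feature_names_in_:
            raise ValueError(
                f"column mismatch: fitted on {self.feature_names_in_}, got {names}")
        lp = Xmat @ self.params_.to_numpy()
        if include_random_effects:
            if groups is None:
                raise ValueError("groups required when include_random_effects=True")
            res = self.residuals_.set_index("cluster")["residual"]
            g = pd.Series(np.asarray(groups))
            unseen = set(g.unique()) - set(res.index)
            if unseen:
                raise ValueError(f"unseen cluster label(s): {sorted(unseen)}")
            lp = lp + res.reindex(g).to_numpy()
        return lp

    def predict_proba(self, X, groups=None, include_random_effects=False):
        return expit(self.decision_function(X, groups, include_random_effects))


def _residual_frame(labels, mean, sd, codes) -> pd.DataFrame:
    n_per = np.bincount(codes, minlength=len(labels)).astype(int)
    return pd.DataFrame({
        "cluster": labels,
        "residual": mean,
        "se": sd,
        "ci_low": mean - 1.96 * sd,
        "ci_high": mean + 1.96 * sd,
        "n_patients": n_per,
    })


def _numerical_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = eps
            ej = np.zeros(d); ej[j] = eps
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / eps ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps ** 2)
    return H


def _safe_inv(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def _split_rhat(x: np.ndarray) -> float:
    """Gelman-Rubin split-Rhat over 4 consecutive segments of one chain."""
    n = (len(x) // 4) * 4
    if n < 8:
        return 1.0
    segs = x[:n].reshape(4, -1)
    m = segs.mean(axis=1)
    w = segs.var(axis=1, ddof=1).mean()
    b = segs.shape[1] * m.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (segs.shape[1] - 1) / segs.shape[1] * w + b / segs.shape[1]
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _draw_variance(rng, resid_ss: float, J: int, cfg: McmcConfig) -> float:
    if cfg.variance_prior == "inverse_gamma":
        shape = cfg.prior_variance_shape + J / 2.0
        scale = cfg.prior_variance_scale + resid_ss / 2.0
    else:  # uniform on the SD: p(sigma2) ~ sigma2^{-1/2}
        shape = (J - 1) / 2.0
        scale = resid_ss / 2.0
        if shape <= 0:
            shape = 0.5
    return float(scale / rng.gamma(shape))


def _gibbs_random_intercept(Xmat, y, codes, J, beta, sigma2, u, cfg, rng):
    p = Xmat.shape[1]
    total = cfg.n_burnin + cfg.n_iter
    keep = cfg.n_iter // cfg.thin
    beta_d = np.empty((keep, p)); s2_d = np.empty(keep)
    u_d = np.empty((keep, J)); dev_d = np.empty(keep)

    su = np.full(J, 0.5)
    sb = np.full(p, 0.1)
    acc_u = np.zeros(J); acc_b = np.zeros(p)
    win = 50
    prior_var_beta = cfg.prior_fixed_sd ** 2

    lp_fixed = Xmat @ beta
    rows_ll = _row_loglik(lp_fixed + u[codes], y)
    cl_ll = np.bincount(codes, weights=rows_ll, minlength=J)

    kept = 0
    batch = 0
    for it in range(total):
        # --- cluster intercepts, vectorised random-walk Metropolis ---
        prop = u + su * rng.standard_normal(J)
        rows_new = _row_loglik(lp_fixed + prop[codes], y)
        cl_new = np.bincount(codes, weights=rows_new, minlength=J)
        log_ratio = (cl_new - cl_ll) + (u ** 2 - prop ** 2) / (2 * sigma2)
        accept = np.log(rng.random(J)) < log_ratio
        u = np.where(accept, prop, u)
        cl_ll = np.where(accept, cl_new, cl_ll)
        acc_u += accept

        # --- fixed effects, componentwise random-walk Metropolis ---
        lp = lp_fixed + u[codes]
        ll_total = cl_ll.sum()
        for k in range(p):
            d = sb[k] * rng.standard_normal()
            lp_prop = lp + d * Xmat[:, k]
            ll_prop = _row_loglik(lp_prop, y).sum()
            bk = beta[k]
            log_ratio = (ll_prop - ll_total
                         + (bk ** 2 - (bk + d) ** 2) / (2 * prior_var_beta))
            if np.log(rng.random()) < log_ratio:
                beta[k] = bk + d
                lp = lp_prop
                ll_total = ll_prop
                acc_b[k] += 1
        lp_fixed = Xmat @ beta
        cl_ll = np.bincount(codes, weights=_row_loglik(lp, y), minlength=J)

        # --- variance, conjugate draw ---
        sigma2 = _draw_variance(rng, float(u @ u), J, cfg)

        # --- adapt proposal scales during burn-in ---
        if it < cfg.n_burnin and (it + 1) % win == 0:
            batch += 1
            g = 1.0 / np.sqrt(batch)
            su *= np.exp(g * (acc_u / win - 0.44))
            sb *= np.exp(g * (acc_b / win - 0.44))
            acc_u[:] = 0; acc_b[:] = 0

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0 and kept < keep:
            beta_d[kept] = beta
            s2_d[kept] = sigma2
            u_d[kept] = u
            dev_d[kept] = -2.0 * ll_total
            kept += 1

    def deviance_at(beta_hat, u_hat):
        return float(-2.0 * _row_loglik(Xmat @ beta_hat + u_hat[codes], y).sum())

    return {"beta": beta_d[:kept], "sigma2": s2_d[:kept], "u": u_d[:kept],
            "deviance": dev_d[:kept], "deviance_at": deviance_at,
            "acceptance": {"scales_u": su, "scales_b": sb}}


def dic(fit) -> dict:
    """DIC = Dbar + pD with pD = Dbar - D(posterior means of beta and u)."""
    draws = getattr(fit, "draws_", None)
    if draws is None or "deviance" not in draws:
        raise ValueError("no retained posterior draws; DIC needs an MCMC fit")
    dbar = float(draws["deviance"].mean())
    beta_hat = draws["beta"].mean(axis=0)
    u_hat = draws["u"].mean(axis=0) if draws["u"].size else np.zeros(0)
    d_at_mean = draws["deviance_at"](beta_hat, u_hat)
    pd_ = dbar - d_at_mean
    return {"dbar": dbar, "d_at_mean": d_at_mean, "pd": pd_, "dic": dbar + pd_}


def shrunken_residuals(fit) -> pd.DataFrame:
    """Per-cluster shrunken residuals: ``cluster, residual, se, ci_low, ci_high, n_patients``.

    ML path: empirical-Bayes posterior means at the ML estimates; MCMC
    path: posterior means and SDs of the intercept draws.  At a
    boundary fit (variance ~ 0) all residuals are exactly 0 with
    zero-width intervals.
    """
    if not getattr(fit, "converged_", False):
        raise ValueError("fit did not converge")
    return fit.residuals_.copy()


def fit_random_intercept_ml(X, y, cluster, n_nodes: int = 15,
                            **kwargs) -> RandomInterceptLogistic:
    """Adaptive-quadrature ML fit of the two-level logistic model."""
    return RandomInterceptLogistic(method="ml", n_quad=n_nodes, **kwargs).fit(
        X, y, cluster)


def fit_random_intercept_mcmc(X, y, cluster, config: McmcConfig | None = None,
                              start=None, **kwargs) -> RandomInterceptLogistic:
    """MCMC fit (Metropolis-within-Gibbs) of the two-level logistic model."""
    return RandomInterceptLogistic(method="mcmc", mcmc=config, **kwargs).fit(
        X, y, cluster, start=start)


def fit_single_level_mcmc(X, y, config: McmcConfig | None = None,
                          add_intercept: bool = True):
    """Bayesian single-level logistic fit, for DIC comparison with model 2.

    Same sampler with the cluster structure removed (no random effects),
    so its DIC is directly comparable with the multilevel DIC.
    """
    cfg = config or McmcConfig()
    cfg.validate()
    Xmat, names = _as_design(X)
    if add_intercept:
        Xmat = np.column_stack([np.ones(len(Xmat)), Xmat])
        names = ["intercept"] + names
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(cfg.seed)
    sl = SingleLevelLogistic(add_intercept=False).fit(
        pd.DataFrame(Xmat, columns=names), y)
    beta = sl.params_.to_numpy().copy()
    p = Xmat.shape[1]
    total = cfg.n_burnin + cfg.n_iter
    keep = cfg.n_iter // cfg.thin
    beta_d = np.empty((keep, p)); dev_d = np.empty(keep)
    sb = np.full(p, 0.1); acc_b = np.zeros(p); win = 50; batch = 0
    prior_var = cfg.prior_fixed_sd ** 2
    lp = Xmat @ beta
    ll = _row_loglik(lp, y).sum()
    kept = 0
    for it in range(total):
        for k in range(p):
            d = sb[k] * rng.standard_normal()
            lp_prop = lp + d * Xmat[:, k]
            ll_prop = _row_loglik(lp_prop, y).sum()
            bk = beta[k]
            if np.log(rng.random()) < (ll_prop - ll
                                       + (bk ** 2 - (bk + d) ** 2) / (2 * prior_var)):
                beta[k] = bk + d; lp = lp_prop; ll = ll_prop; acc_b[k] += 1
        if it < cfg.n_burnin and (it + 1) % win == 0:
            batch += 1
            sb *= np.exp((acc_b / win - 0.44) / np.sqrt(batch))
            acc_b[:] = 0
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0 and kept < keep:
            beta_d[kept] = beta; dev_d[kept] = -2 * ll; kept += 1

    class _Fit:
        pass

    fit = _Fit()
    fit.params_ = pd.Series(beta_d[:kept].mean(axis=0), index=names)
    fit.bse_ = pd.Series(beta_d[:kept].std(axis=0, ddof=1), index=names)
    fit.converged_ = True
    fit.method_ = "mcmc_single_level"
    fit.draws_ = {
        "beta": beta_d[:kept], "u": np.empty((kept, 0)), "deviance": dev_d[:kept],
        "deviance_at": lambda b, u: float(-2 * _row_loglik(Xmat @ b, y).sum()),
    }
    fit.dic_ = dic(fit)["dic"]
    return fit


# ---------------------------------------------------------------------------
# three-level empty model
# ---------------------------------------------------------------------------

@dataclass
class VariancePartition3:
    """Variance partition of the three-level empty model.

    ICCs use the latent-response convention with both higher-level
    variances plus the logistic residual variance pi^2/3 in the
    denominator: ``icc_hosp`` is the hospital share, ``icc_dept`` the
    department share.
    """

    dept_variance: float
    hosp_variance: float
    icc_dept: float
    icc_hosp: float
    dept_variance_interval: tuple[float, float]
    hosp_variance_interval: tuple[float, float]
    dic: float
    draws: dict = field(repr=False, default=None)


def fit_three_level_empty(y, dept, hospital, method: str = "mcmc",
                          config: McmcConfig | None = None) -> VariancePartition3:
    """Intercept-only model with nested department and hospital intercepts.

    Used in the exploratory phase to decide whether the hospital level
    carries any variance worth modelling; requires the MCMC path.
    """
    if method != "mcmc":
        raise ValueError("three-level empty model is only fitted by MCMC")
    cfg = config or McmcConfig()
    cfg.validate()
    y = np.asarray(y, dtype=float).ravel()
    d_codes, d_labels = _encode_groups(dept)
    h_codes, h_labels = _encode_groups(hospital)
    # nesting: each department under exactly one hospital
    hosp_of_dept = np.full(len(d_labels), -1)
    for dc, hc in zip(d_codes, h_codes):
        if hosp_of_dept[dc] == -1:
            hosp_of_dept[dc] = hc
        elif hosp_of_dept[dc] != hc:
            raise ValueError(
                f"department {d_labels[dc]!r} appears under multiple hospitals; "
                "structure is not nested")
    Jd, Jh = len(d_labels), len(h_labels)
    rng = np.random.default_rng(cfg.seed)

    b0 = float(np.log(y.mean() / (1 - y.mean())))
    u = np.zeros(Jd); v = np.zeros(Jh)
    s2d, s2h = 0.1, 0.1
    su = np.full(Jd, 0.5); sv = np.full(Jh, 0.5); sb = 0.1
    acc_u = np.zeros(Jd); acc_v = np.zeros(Jh); acc_b = 0.0
    win = 50; batch = 0
    total = cfg.n_burnin + cfg.n_iter
    keep = cfg.n_iter // cfg.thin
    s2d_d = np.empty(keep); s2h_d = np.empty(keep); dev_d = np.empty(keep)
    b0_d = np.empty(keep)
    u_sum = np.zeros(Jd); v_sum = np.zeros(Jh)
    kept = 0

    def cluster_ll(b0_, u_, v_):
        lp = b0_ + u_[d_codes] + v_[h_codes]
        return _row_loglik(lp, y)

    rows = cluster_ll(b0, u, v)
    for it in range(total):
        # department intercepts
        prop = u + su * rng.standard_normal(Jd)
        rows_new = _row_loglik(b0 + prop[d_codes] + v[h_codes], y)
        dll = (np.bincount(d_codes, weights=rows_new, minlength=Jd)
               - np.bincount(d_codes, weights=rows, minlength=Jd))
        log_ratio = dll + (u ** 2 - prop ** 2) / (2 * s2d)
        accept = np.log(rng.random(Jd)) < log_ratio
        u = np.where(accept, prop, u)
        acc_u += accept
        rows = _row_loglik(b0 + u[d_codes] + v[h_codes], y)

        # hospital intercepts
        prop = v + sv * rng.standard_normal(Jh)
        rows_new = _row_loglik(b0 + u[d_codes] + prop[h_codes], y)
        dll = (np.bincount(h_codes, weights=rows_new, minlength=Jh)
               - np.bincount(h_codes, weights=rows, minlength=Jh))
        log_ratio = dll + (v ** 2 - prop ** 2) / (2 * s2h)
        accept = np.log(rng.random(Jh)) < log_ratio
        v = np.where(accept, prop, v)
        acc_v += accept
        rows = _row_loglik(b0 + u[d_codes] + v[h_codes], y)

        # intercept
        d = sb * rng.standard_normal()
        rows_new = _row_loglik(b0 + d + u[d_codes] + v[h_codes], y)
        if np.log(rng.random()) < rows_new.sum() - rows.sum():
            b0 += d; rows = rows_new; acc_b += 1

        s2d = _draw_variance(rng, float(u @ u), Jd, cfg)
        s2h = _draw_variance(rng, float(v @ v), Jh, cfg)

        if it < cfg.n_burnin and (it + 1) % win == 0:
            batch += 1
            g = 1.0 / np.sqrt(batch)
            su *= np.exp(g * (acc_u / win - 0.44))
            sv *= np.exp(g * (acc_v / win - 0.44))
            sb *= np.exp(g * (acc_b / win - 0.44))
            acc_u[:] = 0; acc_v[:] = 0; acc_b = 0.0

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0 and kept < keep:
            s2d_d[kept] = s2d; s2h_d[kept] = s2h
            b0_d[kept] = b0; dev_d[kept] = -2 * rows.sum()
            u_sum += u; v_sum += v
            kept += 1

    s2d_med = float(np.median(s2d_d[:kept]))
    s2h_med = float(np.median(s2h_d[:kept]))
    total_var = s2d_med + s2h_med + _LOGISTIC_VAR
    dbar = float(dev_d[:kept].mean())
    d_at_mean = float(-2 * cluster_ll(
        float(b0_d[:kept].mean()), u_sum / kept, v_sum / kept).sum())
    return VariancePartition3(
        dept_variance=s2d_med,
        hosp_variance=s2h_med,
        icc_dept=s2d_med / total_var,
        icc_hosp=s2h_med / total_var,
        dept_variance_interval=tuple(np.percentile(s2d_d[:kept], [2.5, 97.5])),
        hosp_variance_interval=tuple(np.percentile(s2h_d[:kept], [2.5, 97.5])),
        dic=2 * dbar - d_at_mean,
        draws={"sigma2_dept": s2d_d[:kept], "sigma2_hosp": s2h_d[:kept],
               "intercept": b0_d[:kept]},
    )


# ---------------------------------------------------------------------------
# random-slope check
# ---------------------------------------------------------------------------

def random_slope_check(X, y, cluster, slope_term: str,
                       config: McmcConfig | None = None) -> dict:
    """Does a covariate's effect vary across clusters?

    Fits an MCMC model with a bivariate (intercept, slope) cluster
    effect under an inverse-Wishart prior on the 2x2 covariance, and
    compares its DIC with the random-intercept model.  The slope
    variation is judged non-substantive when the slope variance's 95%
    credible-interval lower bound is below 0.001 and the DIC does not
    improve by more than 2 — the criterion for a covariate (e.g., a
    case-mix risk score) to qualify as a uniform adjuster.
    """
    cfg = config or McmcConfig()
    cfg.validate()
    if not isinstance(X, pd.DataFrame) or slope_term not in X.columns:
        raise ValueError(f"slope_term {slope_term!r} must be a column of X")
    s = X[slope_term].to_numpy(dtype=float)
    if abs(s.mean()) > 1e-6 * (np.std(s) + 1e-12):
        warnings.warn(
            f"slope term {slope_term!r} is not centred; the intercept variance "
            f"is then the between-cluster variance at {slope_term}=0, which "
            "hampers interpretation", UserWarning)

    base = fit_random_intercept_mcmc(X, y, cluster, config=cfg)

    Xmat, names = _as_design(X)
    Xmat = np.column_stack([np.ones(len(Xmat)), Xmat])
    names = ["intercept"] + names
    yv = np.asarray(y, dtype=float).ravel()
    codes, labels = _encode_groups(cluster)
    J, p = len(labels), Xmat.shape[1]
    rng = np.random.default_rng(cfg.seed + 1)

    beta = base.params_.to_numpy().copy()
    U = np.zeros((J, 2))
    U[:, 0] = base.residuals_["residual"].to_numpy()
    Sigma = np.diag([max(base.dept_variance_, 1e-3), 0.01])
    # prior scale must sit well below the 0.001 substantiveness threshold,
    # or the credible interval's lower bound could never fall under it
    nu0, S0 = 3.0, np.eye(2) * 1e-3

    sU = np.full(J, 0.3); sb = np.full(p, 0.1)
    acc_U = np.zeros(J); acc_b = np.zeros(p)
    win = 50; batch = 0
    total = cfg.n_burnin + cfg.n_iter
    keep = cfg.n_iter // cfg.thin
    s2s_d = np.empty(keep); s2i_d = np.empty(keep); dev_d = np.empty(keep)
    beta_sum = np.zeros(p); U_sum = np.zeros((J, 2))
    kept = 0

    def lp_of(beta_, U_):
        return Xmat @ beta_ + U_[codes, 0] + U_[codes, 1] * s

    rows = _row_loglik(lp_of(beta, U), yv)
    Sinv = np.linalg.inv(Sigma)
    for it in range(total):
        # joint (intercept, slope) proposal per cluster
        prop = U + sU[:, None] * rng.standard_normal((J, 2))
        rows_new = _row_loglik(lp_of(beta, prop), yv)
        dll = (np.bincount(codes, weights=rows_new, minlength=J)
               - np.bincount(codes, weights=rows, minlength=J))
        dprior = -0.5 * (np.einsum("ij,jk,ik->i", prop, Sinv, prop)
                         - np.einsum("ij,jk,ik->i", U, Sinv, U))
        accept = np.log(rng.random(J)) < dll + dprior
        U = np.where(accept[:, None], prop, U)
        acc_U += accept
        rows = _row_loglik(lp_of(beta, U), yv)

        # fixed effects
        lp = lp_of(beta, U)
        ll = rows.sum()
        for k in range(p):
            d = sb[k] * rng.standard_normal()
            lp_prop = lp + d * Xmat[:, k]
            ll_prop = _row_loglik(lp_prop, yv).sum()
            bk = beta[k]
            if np.log(rng.random()) < (ll_prop - ll
                                       + (bk ** 2 - (bk + d) ** 2)
                                       / (2 * cfg.prior_fixed_sd ** 2)):
                beta[k] = bk + d; lp = lp_prop; ll = ll_prop; acc_b[k] += 1
        rows = _row_loglik(lp, yv)

        # covariance, conjugate inverse-Wishart
        Sigma = invwishart.rvs(df=nu0 + J, scale=S0 + U.T @ U, random_state=rng)
        Sinv = np.linalg.inv(Sigma)

        if it < cfg.n_burnin and (it + 1) % win == 0:
            batch += 1
            g = 1.0 / np.sqrt(batch)
            sU *= np.exp(g * (acc_U / win - 0.44))
            sb *= np.exp(g * (acc_b / win - 0.44))
            acc_U[:] = 0; acc_b[:] = 0

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0 and kept < keep:
            s2i_d[kept] = Sigma[0, 0]; s2s_d[kept] = Sigma[1, 1]
            dev_d[kept] = -2 * rows.sum()
            beta_sum += beta; U_sum += U
            kept += 1

    dbar = float(dev_d[:kept].mean())
    slope_var = float(np.median(s2s_d[:kept]))
    interval = tuple(np.percentile(s2s_d[:kept], [2.5, 97.5]))
    d_at_mean = float(-2 * _row_loglik(lp_of(beta_sum / kept, U_sum / kept), yv).sum())
    dic_slope = 2 * dbar - d_at_mean
    dic_base = base.dic_
    substantive = not (interval[0] < 1e-3 and (dic_base - dic_slope) <= 2.0)
    return {
        "slope_variance": slope_var,
        "interval": interval,
        "intercept_variance": float(np.median(s2i_d[:kept])),
        "substantive": substantive,
        "dic": dic_slope,
        "dic_intercept_only": dic_base,
    }
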