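import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gceprofiler import (
    McmcConfig,
    RandomInterceptLogistic,
    SingleLevelLogistic,
    dic,
    fit_random_intercept_mcmc,
    fit_random_intercept_ml,
    fit_three_level_empty,
    random_slope_check,
    shrunken_residuals,
)
from gceprofiler.mlm import marginal_loglik_per_cluster

from conftest import simulate_clustered


def brute_force_cluster_loglik(Xmat, y, codes, J, beta, sigma2, half_width=6.0,
                               n_points=20001):
    """Trapezoid integration of each cluster's marginal likelihood over
    u in [-6 sigma, 6 sigma] — the independent oracle for the quadrature."""
    sigma = np.sqrt(sigma2)
    grid = np.linspace(-half_width * sigma, half_width * sigma, n_points)
    log_prior = -0.5 * np.log(2 * np.pi * sigma2) - grid ** 2 / (2 * sigma2)
    Xb = Xmat @ beta
    out = np.empty(J)
    for j in range(J):
        rows = codes == j
        s = (2 * y[rows] - 1)[:, None]
        ll = -np.logaddexp(0.0, -s * (Xb[rows][:, None] + grid[None, :])).sum(axis=0)
        integrand = np.exp(ll + log_prior)
        out[j] = np.log(np.trapezoid(integrand, grid))
    return out


class TestQuadratureOracle:
    @pytest.mark.parametrize("sigma2", [0.05, 0.115, 0.5])
    def test_marginal_loglik_matches_numeric_integration(self, sigma2, small_glmm):
        X, y, g, _ = small_glmm
        beta = np.array([-1.0, 0.5])
        ours = marginal_loglik_per_cluster(X, y, g, beta, sigma2)
        Xmat = np.column_stack([np.ones(len(y)), X.to_numpy()])
        ref = brute_force_cluster_loglik(Xmat, np.asarray(y, float), g, 15, beta, sigma2)
        np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_quadrature_stable_under_node_doubling(self, small_glmm):
        X, y, g, _ = small_glmm
        beta = np.array([-1.0, 0.5])
        a = marginal_loglik_per_cluster(X, y, g, beta, 0.115, n_quad=15).sum()
        b = marginal_loglik_per_cluster(X, y, g, beta, 0.115, n_quad=30).sum()
        assert abs(a - b) < 1e-6


class TestMlFit:
    def test_matches_lme4_glmer(self, tmp_path, small_glmm):
        """Independent oracle: R lme4::glmer with 15-node adaptive
        quadrature on the same data agrees on beta, the variance and
        the log-likelihood."""
        X, y, g, _ = small_glmm
        fit = fit_random_intercept_ml(X, y, g)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "x": X["x"], "g": g}).to_csv(csv, index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(lme4)); d <- read.csv("{csv}");'
             'm <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15);'
             'cat(fixef(m), as.data.frame(VarCorr(m))$vcov, as.numeric(logLik(m)))'],
            capture_output=True, text=True, timeout=300)
        assert r.returncode == 0, r.stderr
        b0, b1, s2, ll = map(float, r.stdout.split())
        assert fit.params_["intercept"] == pytest.approx(b0, abs=2e-3)
        assert fit.params_["x"] == pytest.approx(b1, abs=2e-3)
        assert fit.dept_variance_ == pytest.approx(s2, abs=5e-3)
        assert fit.loglik_ == pytest.approx(ll, abs=1e-3)

    def test_null_variance_collapses_to_single_level(self):
        """With no true cluster variance the variance estimate sits at or
        near zero and the marginal likelihood matches the single-level
        fit; checked over several seeds since individual estimates
        scatter above zero by sampling noise."""
        estimates, ll_gaps = [], []
        for seed in range(8, 13):
            X, y, g, _ = simulate_clustered(100, 50, sigma2=0.0, seed=seed)
            fit = fit_random_intercept_ml(X, y, g)
            sl = SingleLevelLogistic().fit(X, y)
            estimates.append(fit.dept_variance_)
            ll_gaps.append(abs(fit.loglik_ - sl.loglik_))
        from gceprofiler import icc_latent
        # every estimate corresponds to an ICC below 1%
        assert all(icc_latent(e).icc < 0.01 for e in estimates)
        assert np.median(ll_gaps) < 0.5

    def test_boundary_fit_zeroes_residuals(self):
        """When the variance estimate hits the boundary, the reported
        variance is 0, the fit is flagged, and every shrunken residual
        is exactly 0 with a zero-width interval."""
        X, y, g, _ = simulate_clustered(100, 50, sigma2=0.0, seed=9)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_random_intercept_ml(X, y, g)
        assert fit.boundary_ and fit.dept_variance_ == 0.0
        res = shrunken_residuals(fit)
        assert (res["residual"] == 0).all() and (res["se"] == 0).all()
        assert (res["ci_low"] == 0).all() and (res["ci_high"] == 0).all()

    def test_single_cluster_rejected(self):
        X, y, g, _ = simulate_clustered(1, 50, 0.1, seed=0)
        with pytest.raises(ValueError, match="clusters"):
            fit_random_intercept_ml(X, y, g)

    def test_variance_recovery_and_monotonicity(self):
        """Generative variances 0.05 / 0.115 / 0.5 are recovered (95%
        Wald interval covers truth in most of 6 seeds each) and the
        median estimate is monotone in the truth."""
        medians = []
        for sigma2 in (0.05, 0.115, 0.5):
            est, covered = [], 0
            for seed in range(6):
                X, y, g, _ = simulate_clustered(200, 50, sigma2, seed=100 + seed)
                fit = fit_random_intercept_ml(X, y, g)
                est.append(fit.dept_variance_)
                lo, hi = fit.dept_variance_interval_
                covered += lo <= sigma2 <= hi
            assert covered >= 4, f"interval coverage too low at sigma2={sigma2}"
            medians.append(np.median(est))
        assert medians[0] < medians[1] < medians[2]


class TestShrunkenResiduals:
    def test_eb_residual_matches_numeric_posterior_mean(self):
        """One large cluster with a strong offset: the quadrature EB
        residual agrees with brute-force posterior-mean integration."""
        rng = np.random.default_rng(9)
        n = 10000
        sigma2, offset = 0.3, 0.8
        g = np.r_[np.zeros(n, int), np.ones(200, int)]
        x = rng.standard_normal(len(g))
        lp = -1.0 + 0.4 * x + np.where(g == 0, offset, -0.1)
        y = (rng.random(len(g)) < expit(lp)).astype(int)
        X = pd.DataFrame({"x": x})
        fit = fit_random_intercept_ml(X, y, g)

        beta = fit.params_.to_numpy()
        s2 = fit.dept_variance_
        Xmat = np.column_stack([np.ones(len(g)), x])
        grid = np.linspace(-6 * np.sqrt(s2), 6 * np.sqrt(s2), 20001)
        rows = g == 0
        s = (2 * y[rows] - 1)[:, None]
        ll = -np.logaddexp(0, -s * ((Xmat[rows] @ beta)[:, None] + grid[None, :])).sum(axis=0)
        logw = ll - grid ** 2 / (2 * s2)
        w = np.exp(logw - logw.max())
        numeric_mean = np.trapezoid(w * grid, grid) / np.trapezoid(w, grid)

        eb = shrunken_residuals(fit).set_index("cluster").loc[0, "residual"]
        assert eb == pytest.approx(numeric_mean, abs=0.01)

    def test_shrinkage_towards_zero(self):
        """Every EB residual is smaller in magnitude than the
        corresponding cluster-dummy fixed-effect offset."""
        X, y, g, _ = simulate_clustered(30, 100, 0.3, beta0=-0.8, seed=10)
        fit = fit_random_intercept_ml(X, y, g)
        # fixed-effect offsets: per-cluster intercepts, no global intercept
        dummies = pd.get_dummies(pd.Series(g), prefix="c").astype(float)
        Xd = pd.concat([X.reset_index(drop=True), dummies], axis=1)
        fe = SingleLevelLogistic(add_intercept=False).fit(Xd, y)
        alpha = fe.params_[[f"c_{j}" for j in range(30)]].to_numpy()
        offsets = alpha - fit.params_["intercept"]
        res = shrunken_residuals(fit).sort_values("cluster")["residual"].to_numpy()
        assert (np.abs(res) <= np.abs(offsets) + 1e-9).all()

    def test_residuals_sum_near_zero_on_balanced_design(self):
        X, y, g, _ = simulate_clustered(100, 50, 0.2, seed=11)
        fit = fit_random_intercept_ml(X, y, g)
        assert abs(shrunken_residuals(fit)["residual"].sum()) < 0.05


class TestMcmc:
    CFG = dict(n_burnin=600, n_iter=3000, thin=5)

    def test_seeded_chain_is_reproducible(self, small_glmm):
        X, y, g, _ = small_glmm
        cfg = McmcConfig(seed=5, **self.CFG)
        a = fit_random_intercept_mcmc(X, y, g, config=cfg)
        b = fit_random_intercept_mcmc(X, y, g, config=cfg)
        assert a.dept_variance_ == b.dept_variance_
        assert a.dic_ == b.dic_
        pd.testing.assert_series_equal(a.params_, b.params_)
        np.testing.assert_array_equal(a.draws_["sigma2"], b.draws_["sigma2"])

    def test_agrees_with_ml_on_large_balanced_data(self):
        X, y, g, _ = simulate_clustered(200, 50, 0.115, seed=12)
        ml = fit_random_intercept_ml(X, y, g)
        mc = fit_random_intercept_mcmc(
            X, y, g, config=McmcConfig(seed=1, **self.CFG), start=ml)
        assert mc.dept_variance_ == pytest.approx(ml.dept_variance_, abs=0.05)
        for term in ml.params_.index:
            assert abs(mc.params_[term] - ml.params_[term]) < 2 * mc.bse_[term]

    def test_credible_interval_contains_median(self, small_glmm):
        X, y, g, _ = small_glmm
        fit = fit_random_intercept_mcmc(X, y, g, config=McmcConfig(seed=3, **self.CFG))
        lo, hi = fit.dept_variance_interval_
        assert lo <= fit.dept_variance_ <= hi

    def test_uniform_sd_prior_runs(self, small_glmm):
        X, y, g, _ = small_glmm
        cfg = McmcConfig(seed=3, variance_prior="uniform_sd", **self.CFG)
        fit = fit_random_intercept_mcmc(X, y, g, config=cfg)
        assert fit.dept_variance_ > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            McmcConfig(n_iter=-1).validate()
        with pytest.raises(ValueError, match="prior"):
            McmcConfig(prior_variance_shape=0.0).validate()


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self, small_glmm):
        X, y, g, _ = small_glmm
        fit = fit_random_intercept_mcmc(
            X, y, g, config=McmcConfig(seed=5, n_burnin=200, n_iter=500, thin=5))
        # collapse the posterior to a single point
        fit.draws_["beta"] = np.repeat(fit.draws_["beta"][:1], 50, axis=0)
        fit.draws_["u"] = np.repeat(fit.draws_["u"][:1], 50, axis=0)
        d0 = fit.draws_["deviance_at"](fit.draws_["beta"][0], fit.draws_["u"][0])
        fit.draws_["deviance"] = np.full(50, d0)
        res = dic(fit)
        assert res["pd"] == pytest.approx(0.0, abs=1e-9)
        assert res["dic"] == pytest.approx(res["d_at_mean"], abs=1e-9)

    def test_pd_nonnegative_on_standard_fit(self, small_glmm):
        X, y, g, _ = small_glmm
        fit = fit_random_intercept_mcmc(
            X, y, g, config=McmcConfig(seed=6, n_burnin=600, n_iter=3000, thin=5))
        assert dic(fit)["pd"] >= 0

    def test_missing_draws_rejected(self, small_glmm):
        X, y, g, _ = small_glmm
        fit = fit_random_intercept_ml(X, y, g)
        with pytest.raises(ValueError, match="draws"):
            dic(fit)


class TestThreeLevel:
    CFG = McmcConfig(n_burnin=800, n_iter=3000, thin=3, seed=0)

    @staticmethod
    def _nested(n_hosp, depts_per_hosp, n_per, s2h, s2d, seed):
        rng = np.random.default_rng(seed)
        n_dept = n_hosp * depts_per_hosp
        v = rng.normal(0, np.sqrt(s2h), n_hosp)
        u = rng.normal(0, np.sqrt(s2d), n_dept)
        dept = np.repeat(np.arange(n_dept), n_per)
        hosp = dept // depts_per_hosp
        y = (rng.random(len(dept)) < expit(-1.5 + u[dept] + v[hosp])).astype(int)
        return y, dept, hosp

    def test_recovers_hospital_variance(self):
        covered = 0
        for seed in range(3):
            y, dept, hosp = self._nested(30, 5, 40, s2h=0.3, s2d=0.05, seed=seed)
            part = fit_three_level_empty(y, dept, hosp, config=self.CFG)
            lo, hi = part.hosp_variance_interval
            covered += lo <= 0.3 <= hi
        assert covered >= 2

    def test_null_hospital_variance_gives_tiny_icc(self):
        small = 0
        for seed in range(5):
            y, dept, hosp = self._nested(30, 5, 40, s2h=0.0, s2d=0.3, seed=50 + seed)
            part = fit_three_level_empty(y, dept, hosp, config=self.CFG)
            small += part.icc_hosp < 0.01
        assert small >= 4

    def test_icc_partition_uses_both_variances(self):
        y, dept, hosp = self._nested(20, 4, 30, s2h=0.2, s2d=0.2, seed=1)
        part = fit_three_level_empty(y, dept, hosp, config=self.CFG)
        total = part.dept_variance + part.hosp_variance + np.pi ** 2 / 3
        assert part.icc_dept == pytest.approx(part.dept_variance / total)
        assert part.icc_hosp == pytest.approx(part.hosp_variance / total)

    def test_non_nested_structure_rejected(self):
        y = np.array([0, 1, 0, 1])
        dept = np.array([0, 0, 0, 1])
        hosp = np.array([0, 0, 1, 1])  # dept 0 under two hospitals
        with pytest.raises(ValueError, match="nested"):
            fit_three_level_empty(y, dept, hosp)

    def test_ml_path_refused(self):
        y, dept, hosp = self._nested(10, 2, 20, 0.1, 0.1, seed=2)
        with pytest.raises(ValueError, match="MCMC"):
            fit_three_level_empty(y, dept, hosp, method="ml")


class TestRandomSlope:
    # chains long enough that Monte-Carlo error in DIC stays well under
    # the +/-2 decision band
    CFG = McmcConfig(n_burnin=2000, n_iter=12000, thin=4, seed=0)

    def test_null_slope_not_substantive(self):
        hits = 0
        for seed in range(2):
            X, y, g, _ = simulate_clustered(50, 60, 0.2, seed=200 + seed)
            X["x"] -= X["x"].mean()
            res = random_slope_check(X, y, g, "x", config=self.CFG)
            hits += not res["substantive"]
        assert hits == 2

    def test_large_slope_variance_detected(self):
        X, y, g, _ = simulate_clustered(100, 60, 0.2, seed=210, slope_sd=np.sqrt(0.3))
        X["x"] -= X["x"].mean()
        res = random_slope_check(X, y, g, "x", config=self.CFG)
        assert res["substantive"]
        assert res["slope_variance"] > 0.05

    def test_uncentred_slope_term_warns(self):
        X, y, g, _ = simulate_clustered(30, 30, 0.1, seed=220)
        X = X + 5.0
        with pytest.warns(UserWarning, match="not centred"):
            random_slope_check(X, y, g, "x",
                               config=McmcConfig(n_burnin=200, n_iter=400,
                                                 thin=4, seed=0))
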