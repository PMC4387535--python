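import numpy as np
import pytest
from scipy.special import k1
from scipy.stats import multivariate_normal, norm

import u5mbg as m
from u5mbg.stgp import chol_with_jitter, st_cov


def _random_instance(n, seed, model=None):
    rng = np.random.default_rng(seed)
    lonlat = rng.uniform(0, 5, (n, 2))
    times = rng.integers(0, 3, n).astype(float)
    model = model or m.STGPModel(
        beta={"intercept": 0.2, "x1": 0.05}, sigma2=3e-3,
        kappa=np.sqrt(8.0) / 2.0, nugget=1.5e-3, rho=-0.4)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    beta = np.array([model.beta["intercept"], model.beta["x1"]])
    K = m.build_cov_matrix(lonlat, times, model)
    y = X @ beta + np.linalg.cholesky(K) @ rng.standard_normal(n)
    return model, X, y, lonlat, times


class TestMaternCovariance:
    def test_zero_distance_is_marginal_variance(self):
        assert m.matern_cov(0.0, 2.5, 0.7) == 2.5

    def test_nu1_closed_form_against_bessel(self):
        # sigma2 (kappa h) K_1(kappa h) at kappa = h = 1
        assert abs(m.matern_cov(1.0, 1.0, 1.0) - k1(1.0)) < 1e-12
        assert abs(m.matern_cov(1.0, 1.0, 1.0) - 0.60191) < 1e-5

    def test_strictly_decreasing_in_distance(self):
        h = np.linspace(0.01, 10, 200)
        c = m.matern_cov(h, 1.0, 1.3)
        assert np.all(np.diff(c) < 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            m.matern_cov(-0.1, 1.0, 1.0)


class TestNominalRange:
    def test_field_scale_value(self):
        # kappa from the log-scale estimate -0.47 gives ~4.525 degrees
        assert abs(m.range_from_kappa(np.exp(-0.47)) - 4.525) < 1e-3

    def test_sqrt8_gives_unit_range(self):
        assert abs(m.range_from_kappa(np.sqrt(8.0)) - 1.0) < 1e-12

    def test_monotone_decreasing_in_kappa(self):
        ks = np.linspace(0.1, 5, 50)
        rs = [m.range_from_kappa(k) for k in ks]
        assert all(a > b for a, b in zip(rs, rs[1:]))


class TestSpaceTimeCovariance:
    def setup_method(self):
        self.model = m.STGPModel(beta={"intercept": 0.0}, sigma2=2.0,
                                 kappa=1.0, nugget=0.1, rho=-0.47)

    def test_zero_lag_reduces_to_matern(self):
        for h in (0.0, 0.5, 2.0):
            assert st_cov(h, 0, self.model) == m.matern_cov(h, 2.0, 1.0)

    def test_one_wave_lag_scales_by_rho(self):
        assert abs(st_cov(0.0, 1, self.model) - (-0.47 * 2.0)) < 1e-12

    def test_rho_zero_kills_cross_wave_covariance(self):
        model = m.STGPModel(beta={"intercept": 0.0}, sigma2=2.0, kappa=1.0,
                            nugget=0.0, rho=0.0)
        assert st_cov(1.0, 1, model) == 0.0
        assert st_cov(1.0, 0, model) == m.matern_cov(1.0, 2.0, 1.0)


class TestCovarianceMatrix:
    def test_coincident_points_same_wave(self):
        model = m.STGPModel(beta={"intercept": 0.0}, sigma2=2.0, kappa=1.0,
                            nugget=0.3, rho=0.0)
        K = m.build_cov_matrix(np.zeros((2, 2)), np.zeros(2), model)
        assert K[0, 1] == 2.0
        assert K[0, 0] == 2.3

    def test_matches_elementwise_scalar_oracle(self):
        model, X, y, lonlat, times = _random_instance(20, seed=2)
        K = m.build_cov_matrix(lonlat, times, model)
        for i in range(20):
            for j in range(20):
                h = np.hypot(*(lonlat[i] - lonlat[j]))
                expected = st_cov(h, times[i] - times[j], model)
                if i == j:
                    expected += model.nugget
                assert abs(K[i, j] - expected) < 1e-12

    def test_positive_definite_on_random_instances(self):
        for seed in range(10):
            model, X, y, lonlat, times = _random_instance(30, seed=seed)
            K = m.build_cov_matrix(lonlat, times, model)
            assert np.linalg.eigvalsh(K).min() > 0


class TestLogMarginalLikelihood:
    def test_matches_dense_multivariate_normal(self):
        model, X, y, lonlat, times = _random_instance(30, seed=4)
        beta = np.array([model.beta["intercept"], model.beta["x1"]])
        K = m.build_cov_matrix(lonlat, times, model)
        direct = multivariate_normal.logpdf(y, mean=X @ beta, cov=K)
        ours = m.log_marginal_likelihood(model, X, y, lonlat, times)
        assert abs(ours - direct) < 1e-8

    def test_iid_limit_is_sum_of_normal_densities(self):
        n = 50
        rng = np.random.default_rng(7)
        y = rng.normal(0, 0.2, n)
        model = m.STGPModel(beta={"intercept": 0.0}, sigma2=0.0, kappa=1.0,
                            nugget=0.04, rho=0.0)
        X = np.ones((n, 1))
        lonlat = rng.uniform(0, 5, (n, 2))
        ours = m.log_marginal_likelihood(model, X, y, lonlat, np.zeros(n))
        direct = norm.logpdf(y, 0.0, 0.2).sum()
        assert abs(ours - direct) < 1e-8

    def test_perfect_fit_beats_perturbed_coefficients(self):
        n = 40
        rng = np.random.default_rng(8)
        lonlat = rng.uniform(0, 5, (n, 2))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = {"intercept": 0.2, "x1": 0.1}
        model = m.STGPModel(beta=beta, sigma2=0.0, kappa=1.0, nugget=1e-8, rho=0.0)
        y = X @ np.array([0.2, 0.1])
        ll0 = m.log_marginal_likelihood(model, X, y, lonlat, np.zeros(n))
        for db in (0.01, -0.01):
            pert = m.STGPModel(beta={"intercept": 0.2 + db, "x1": 0.1},
                               sigma2=0.0, kappa=1.0, nugget=1e-8, rho=0.0)
            assert ll0 > m.log_marginal_likelihood(pert, X, y, lonlat, np.zeros(n))

    def test_single_wave_likelihood_ignores_rho(self):
        """With all data in one wave the AR(1) coefficient cannot matter."""
        model, X, y, lonlat, _ = _random_instance(25, seed=9)
        t = np.zeros(25)
        lls = []
        for rho in (0.0, 0.5, -0.8):
            mdl = m.STGPModel(beta=model.beta, sigma2=model.sigma2,
                              kappa=model.kappa, nugget=model.nugget, rho=rho)
            lls.append(m.log_marginal_likelihood(mdl, X, y, lonlat, t))
        assert max(lls) - min(lls) < 1e-10

    def test_rho_zero_factorizes_over_waves(self):
        """rho = 0 makes waves independent: the joint loglik equals the sum
        of per-wave purely spatial logliks."""
        model, X, y, lonlat, times = _random_instance(30, seed=10)
        mdl = m.STGPModel(beta=model.beta, sigma2=model.sigma2,
                          kappa=model.kappa, nugget=model.nugget, rho=0.0)
        joint = m.log_marginal_likelihood(mdl, X, y, lonlat, times)
        parts = 0.0
        for w in np.unique(times):
            sel = times == w
            parts += m.log_marginal_likelihood(
                mdl, X[sel], y[sel], lonlat[sel], np.zeros(sel.sum()))
        assert abs(joint - parts) < 1e-6


class TestKrigingPrediction:
    def test_exactness_at_observed_point_without_nugget(self):
        n = 40
        rng = np.random.default_rng(12)
        lonlat = rng.uniform(0, 4, (n, 2))
        times = np.zeros(n)
        model = m.STGPModel(beta={"intercept": 0.2}, sigma2=3e-3,
                            kappa=np.sqrt(8.0) / 2.0, nugget=0.0, rho=0.0)
        X = np.ones((n, 1))
        K = m.build_cov_matrix(lonlat, times, model)
        y = 0.2 + np.linalg.cholesky(K + 1e-12 * np.eye(n)) @ rng.standard_normal(n)
        fr = _manual_fit_result(model, X, y, lonlat, times)
        mu, var = m.predict_points(fr, X[:5], lonlat[:5], times[:5],
                                   include_beta_uncertainty=False)
        np.testing.assert_allclose(mu, y[:5], atol=1e-8)
        assert np.all(var <= 1e-10)

    def test_decorrelation_limit_returns_trend_and_marginal_variance(self):
        model, X, y, lonlat, times = _random_instance(30, seed=13)
        fr = _manual_fit_result(model, X, y, lonlat, times)
        far = np.array([[500.0, 500.0]])
        Xnew = np.array([[1.0, 0.3]])
        mu, var = m.predict_points(fr, Xnew, far, np.array([0.0]),
                                   include_beta_uncertainty=False)
        beta = np.array([model.beta["intercept"], model.beta["x1"]])
        assert abs(mu[0] - Xnew @ beta) < 1e-10
        assert abs(var[0] - model.sigma2) < 1e-10

    def test_mean_and_variance_match_bruteforce_oracle(self):
        """Kriging equations vs an explicit-inverse scalar implementation."""
        model, X, y, lonlat, times = _random_instance(30, seed=14)
        fr = _manual_fit_result(model, X, y, lonlat, times)
        rng = np.random.default_rng(15)
        new_lonlat = rng.uniform(0, 5, (12, 2))
        new_t = rng.integers(0, 3, 12).astype(float)
        Xnew = np.column_stack([np.ones(12), rng.standard_normal(12)])
        mu, var = m.predict_points(fr, Xnew, new_lonlat, new_t,
                                   include_beta_uncertainty=False)
        beta = np.array([model.beta["intercept"], model.beta["x1"]])
        K = m.build_cov_matrix(lonlat, times, model)
        Kinv = np.linalg.inv(K)
        for i in range(12):
            k = np.array([st_cov(np.hypot(*(new_lonlat[i] - lonlat[j])),
                                 new_t[i] - times[j], model)
                          for j in range(len(y))])
            mu_o = Xnew[i] @ beta + k @ Kinv @ (y - X @ beta)
            var_o = model.sigma2 - k @ Kinv @ k
            assert abs(mu[i] - mu_o) < 1e-8
            assert abs(var[i] - var_o) < 1e-8

    def test_variance_grows_with_distance_on_transect(self):
        """Radial design: prediction variance is non-decreasing moving away
        from the data."""
        model = m.STGPModel(beta={"intercept": 0.2}, sigma2=3e-3,
                            kappa=np.sqrt(8.0) / 2.0, nugget=1e-3, rho=0.0)
        rng = np.random.default_rng(16)
        ang = rng.uniform(0, 2 * np.pi, 60)
        rad = rng.uniform(0, 0.5, 60)
        lonlat = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        times = np.zeros(60)
        X = np.ones((60, 1))
        y = 0.2 + 0.05 * rng.standard_normal(60)
        fr = _manual_fit_result(model, X, y, lonlat, times)
        transect = np.column_stack([np.linspace(0.6, 6.0, 40), np.zeros(40)])
        _, var = m.predict_points(fr, np.ones((40, 1)), transect, np.zeros(40),
                                  include_beta_uncertainty=False)
        assert np.all(np.diff(var) >= -1e-12)

    def test_permutation_invariance(self):
        model, X, y, lonlat, times = _random_instance(40, seed=17)
        fr = _manual_fit_result(model, X, y, lonlat, times)
        perm = np.random.default_rng(18).permutation(40)
        fr2 = _manual_fit_result(model, X[perm], y[perm], lonlat[perm], times[perm])
        new = np.array([[2.0, 2.0]])
        Xn = np.array([[1.0, 0.1]])
        mu1, v1 = m.predict_points(fr, Xn, new, np.array([1.0]))
        mu2, v2 = m.predict_points(fr2, Xn, new, np.array([1.0]))
        assert abs(mu1[0] - mu2[0]) < 1e-10
        assert abs(v1[0] - v2[0]) < 1e-10
        ll1 = m.log_marginal_likelihood(model, X, y, lonlat, times)
        ll2 = m.log_marginal_likelihood(model, X[perm], y[perm], lonlat[perm],
                                        times[perm])
        assert abs(ll1 - ll2) < 1e-8


class TestFit:
    def test_pure_noise_data_shrinks_spatial_variance(self, stack25):
        """Generated with sigma2 = 0: fitted beta lands within 3 SE and the
        spatial variance collapses relative to the nugget."""
        model = m.STGPModel(beta={"intercept": 0.2, "accessibility": 0.03},
                            sigma2=0.0, kappa=1.0, nugget=2.5e-3, rho=0.0)
        ok_beta = ok_var = 0
        n_rep = 5
        for rep in range(n_rep):
            clusters, _ = m.simulate_survey(stack25, model, 300, 1, seed=40 + rep)
            fr = m.fit(clusters, stack25, ["accessibility"],
                       m.FitConfig(n_starts=2, seed=rep))
            s = fr.summaries
            z = abs(s.loc["accessibility", "mean"] - 0.03) / s.loc["accessibility", "sd"]
            ok_beta += z < 3
            ok_var += fr.model.sigma2 < fr.model.nugget / 10
        assert ok_beta >= n_rep - 1
        assert ok_var >= n_rep - 1

    def test_strong_field_parameters_recovered(self, stack25, strong_model, toy_clusters):
        clusters, _ = toy_clusters
        fr = m.fit(clusters, stack25, ["accessibility"], m.FitConfig(n_starts=2))
        assert fr.convergence["status"] == "converged"
        # generous bands: n = 80 is a small survey
        assert 0.1 < fr.model.range_deg / strong_model.range_deg < 10
        q = fr.summaries
        assert (q["q05"] <= q["q50"]).all() and (q["q50"] <= q["q95"]).all()

    def test_refuses_tiny_surveys(self, stack25, toy_clusters):
        clusters, _ = toy_clusters
        with pytest.raises(ValueError, match="at least 50"):
            m.fit(clusters.head(20), stack25, ["accessibility"])

    def test_missing_covariate_rejected(self, stack25, toy_clusters):
        clusters, _ = toy_clusters
        with pytest.raises(ValueError, match="not in stack"):
            m.fit(clusters, stack25, ["no_such_layer"])


class TestPredictSurface:
    def test_bounds_ordered_and_in_unit_interval(self, stack25, toy_fit):
        surf = m.predict(toy_fit, stack25, wave=1)
        ok = np.isfinite(surf.mean)
        assert np.all(surf.lower[ok] <= surf.mean[ok] + 1e-12)
        assert np.all(surf.mean[ok] <= surf.upper[ok] + 1e-12)
        assert surf.mean[ok].min() >= 0 and surf.mean[ok].max() <= 1

    def test_wave_far_from_observations_rejected(self, stack25, toy_fit):
        with pytest.raises(ValueError, match="wave"):
            m.predict(toy_fit, stack25, wave=5)


class TestModelComparison:
    def test_duplicate_fits_tie(self, toy_fit):
        tbl = m.compare_models([toy_fit, toy_fit])
        assert len(tbl) == 2
        assert abs(tbl["dic"].iloc[0] - tbl["dic"].iloc[1]) < 1e-12

    def test_mismatched_responses_rejected(self, stack25, toy_fit, toy_clusters):
        clusters, _ = toy_clusters
        other, _ = m.simulate_survey(stack25, toy_fit.model, 80, 2, seed=99)
        fr2 = m.fit(other, stack25, ["accessibility"], m.FitConfig(n_starts=1))
        with pytest.raises(ValueError, match="identical response"):
            m.compare_models([toy_fit, fr2])


def _manual_fit_result(model, X, y, lonlat, times):
    """FitResult shell around known parameters (no optimisation), so the
    prediction equations can be tested in isolation."""
    import pandas as pd

    return m.FitResult(model=model, summaries=pd.DataFrame(), loglik=np.nan,
                       dic=np.nan, p_d=np.nan, marginal_lik_note="",
                       convergence={}, X=X, y=y, lonlat=lonlat,
                       times=np.asarray(times, dtype=float),
                       covariates=[c for c in model.beta if c != "intercept"])
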