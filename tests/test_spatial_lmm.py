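"""Likelihood correctness, classical-test equivalence, and fit behavior.

Brute-force oracles are implemented here, independently of the package: the
dense MVN log-density via explicit inverse and determinant, and the
restricted likelihood via an orthonormal contrast basis. Two REML fits are
additionally checked against values obtained from R's nlme::gls with an
exponential correlation structure and nugget (frozen below).
"""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from stlmm import (
    CovarianceParams,
    DesignSpec,
    aic,
    exponential_covariance,
    fit_nonspatial,
    fit_spatial,
    make_layout,
    marginal_loglik,
    reml_loglik,
    wald_test,
)


def dense_mvn_loglik(y, mu, V):
    """Naive MVN log-density: explicit inverse and determinant."""
    n = len(y)
    r = y - mu
    return -0.5 * (
        n * np.log(2 * np.pi) + np.log(np.linalg.det(V)) + r @ np.linalg.inv(V) @ r
    )


def contrast_reml_loglik(y, X, V):
    """REML from the definition: density of orthonormal error contrasts."""
    Q, _ = np.linalg.qr(X, mode="complete")
    K = Q[:, X.shape[1]:]
    return dense_mvn_loglik(K.T @ y, np.zeros(K.shape[1]), K.T @ V @ K)


def random_instance(rng, n):
    coords = rng.uniform(0, 5, (n, 2))
    D = squareform(pdist(coords))
    ind = np.zeros(n)
    ind[rng.choice(n, n // 2, replace=False)] = 1.0
    design = DesignSpec(ind)
    params = CovarianceParams(
        tau2=rng.uniform(0.1, 2.0), rho=rng.uniform(0.5, 3.0), sigma2=rng.uniform(0.1, 2.0)
    )
    y = rng.normal(0, 1, n)
    return y, design, params, D


class TestExponentialCovariance:
    def test_off_diagonal_formula(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        V = exponential_covariance(D, CovarianceParams(2.0, 5.0, 0.0))
        assert V[0, 1] == pytest.approx(2.0 * np.exp(-1.0), abs=1e-9)

    def test_diagonal_is_sill_plus_nugget(self):
        D = np.zeros((3, 3))
        V = exponential_covariance(D + 1.0 - np.eye(3), CovarianceParams(2.0, 5.0, 1.0))
        np.testing.assert_allclose(np.diag(V), 3.0)

    def test_zero_sill_gives_nugget_identity(self):
        D = squareform(pdist(np.random.default_rng(0).uniform(0, 3, (5, 2))))
        V = exponential_covariance(D, CovarianceParams(0.0, 1.0, 1.5))
        np.testing.assert_allclose(V, 1.5 * np.eye(5))

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            CovarianceParams(1.0, 0.0, 1.0)

    def test_monotone_in_distance_and_range(self):
        p = CovarianceParams(1.0, 2.0, 0.0)
        d = np.linspace(0.1, 10, 50)
        vals = p.tau2 * np.exp(-d / p.rho)
        assert np.all(np.diff(vals) < 0)
        rhos = np.linspace(0.5, 8, 30)
        at_fixed_d = [r_tau * np.exp(-3.0 / r) for r, r_tau in zip(rhos, [1.0] * 30)]
        assert np.all(np.diff(at_fixed_d) > 0)


class TestCovarianceProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        tau2=st.floats(0.01, 10.0),
        rho=st.floats(0.1, 50.0),
        d1=st.floats(0.01, 20.0),
        delta=st.floats(0.01, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_kernel_strictly_decreasing_in_distance(self, tau2, rho, d1, delta):
        p = CovarianceParams(tau2, rho, 0.0)
        D = np.array([[0.0, d1], [d1, 0.0]])
        D2 = np.array([[0.0, d1 + delta], [d1 + delta, 0.0]])
        assert exponential_covariance(D2, p)[0, 1] < exponential_covariance(D, p)[0, 1]

    @given(
        tau2=st.floats(0.01, 10.0),
        rho=st.floats(0.1, 50.0),
        d=st.floats(0.01, 20.0),
        factor=st.floats(1.1, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_kernel_strictly_increasing_in_range(self, tau2, rho, d, factor):
        D = np.array([[0.0, d], [d, 0.0]])
        lo = exponential_covariance(D, CovarianceParams(tau2, rho, 0.0))[0, 1]
        hi = exponential_covariance(D, CovarianceParams(tau2, rho * factor, 0.0))[0, 1]
        assert hi > lo


class TestLoglikOracles:
    def test_marginal_matches_dense_oracle_100_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(6, 13))
            y, design, params, D = random_instance(rng, n)
            beta = rng.normal(0, 1, 2)
            ours = marginal_loglik(y, design, params, D, beta)
            V = exponential_covariance(D, params)
            oracle = dense_mvn_loglik(y, design.matrix @ beta, V)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_reml_matches_contrast_oracle_100_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(6, 13))
            y, design, params, D = random_instance(rng, n)
            ours = reml_loglik(y, design, params, D)
            V = exponential_covariance(D, params)
            oracle = contrast_reml_loglik(y, design.matrix, V)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_marginal_zero_mean_iid_closed_form(self):
        # V = I, y = X beta: density reduces to -n/2 ln(2 pi)
        n = 6
        D = squareform(pdist(np.arange(n, dtype=float)[:, None] * [1, 0]))
        ind = np.array([1.0, 1, 1, 0, 0, 0])
        design = DesignSpec(ind)
        beta = np.array([0.3, -0.2])
        y = design.matrix @ beta
        ll = marginal_loglik(y, design, CovarianceParams(0.0, 1.0, 1.0), D, beta)
        assert ll == pytest.approx(-0.5 * n * np.log(2 * np.pi), abs=1e-10)

    def test_reml_iid_closed_form(self):
        # tau2 = 0: REML equals the closed-form Gaussian linear-model value
        rng = np.random.default_rng(9)
        n = 8
        coords = rng.uniform(0, 4, (n, 2))
        D = squareform(pdist(coords))
        ind = np.zeros(n)
        ind[:4] = 1.0
        design = DesignSpec(ind)
        y = rng.normal(0, 1, n)
        sigma2 = 0.7
        X = design.matrix
        beta_ols, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta_ols) ** 2))
        p = 2
        closed = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + rss / sigma2)
        ours = reml_loglik(y, design, CovarianceParams(0.0, 1.0, sigma2), D)
        assert ours == pytest.approx(closed, abs=1e-8)

    def test_reml_invariant_to_constant_shift(self):
        rng = np.random.default_rng(10)
        y, design, params, D = random_instance(rng, 10)
        a = reml_loglik(y, design, params, D)
        b = reml_loglik(y + 17.3, design, params, D)
        assert a == pytest.approx(b, abs=1e-8)


class TestNonspatialFit:
    def test_equals_pooled_two_sample_t(self):
        y = np.array([1.0, 2, 3, 2, 3, 4])
        ind = np.array([1.0, 1, 1, 0, 0, 0])
        fit = fit_nonspatial(y, DesignSpec(ind))
        w = wald_test(fit)
        assert fit.beta[1] == pytest.approx(-1.0, abs=1e-12)
        assert w.se == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)
        assert w.statistic == pytest.approx(-1.2247448713915885, abs=1e-10)
        assert w.p_value == pytest.approx(0.2878641347266907, abs=1e-10)

    def test_matches_scipy_ttest_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n1, n0 = int(rng.integers(3, 15)), int(rng.integers(3, 15))
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.3, 1, n0)
            y = np.concatenate([a, b])
            ind = np.concatenate([np.ones(n1), np.zeros(n0)])
            w = wald_test(fit_nonspatial(y, DesignSpec(ind)))
            t_ref, p_ref = stats.ttest_ind(a, b)
            assert w.statistic == pytest.approx(t_ref, abs=1e-10)
            assert w.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_zero_residual_flags_degenerate(self):
        ind = np.array([1.0, 1, 0, 0])
        fit = fit_nonspatial(ind.copy(), DesignSpec(ind))
        assert fit.degenerate and fit.converged
        assert wald_test(fit).p_value is None

    def test_aic_identity(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 12)
        ind = np.zeros(12)
        ind[:6] = 1
        fit = fit_nonspatial(y, DesignSpec(ind))
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.loglik_ml, abs=1e-9)
        assert aic(fit) == pytest.approx(fit.aic, abs=1e-12)


def _sim_spatial(rng, n_side=8, tau2=1.0, rho=2.0, sigma2=0.25):
    coords = make_layout("squaregrid", n_side, n_side)
    D = squareform(pdist(coords))
    n = n_side * n_side
    L = np.linalg.cholesky(np.exp(-D / rho) + 1e-10 * np.eye(n))
    y = np.sqrt(tau2) * (L @ rng.normal(0, 1, n)) + rng.normal(0, np.sqrt(sigma2), n)
    ind = (coords[:, 0] < n_side / 2).astype(float)
    return y, DesignSpec(ind), D


class TestSpatialFit:
    # REML estimates from R nlme::gls(y ~ g, corExp(form=~x+y, nugget=TRUE),
    # method="REML") on two replicates of the seed-42 generator below
    NLME = [
        dict(tau2=0.9175, rho=2.5541, sigma2=0.2203, beta1=-0.0046, se=0.3780),
        dict(tau2=0.9346, rho=0.9835, sigma2=0.0000, beta1=0.19365, se=0.32566),
    ]

    def test_reml_fit_matches_nlme_gls(self):
        coords = make_layout("squaregrid", 10, 10)
        D = squareform(pdist(coords))
        L = np.linalg.cholesky(np.exp(-D / 2.0) + 1e-10 * np.eye(100))
        ind = (coords[:, 0] < 5).astype(float)
        design = DesignSpec(ind)
        rng = np.random.default_rng(42)
        for i, ref in enumerate(self.NLME):
            y = L @ rng.normal(0, 1, 100) + rng.normal(0, 0.5, 100)
            fit = fit_spatial(y, design, D, rng=i)
            assert fit.converged
            assert fit.params.tau2 == pytest.approx(ref["tau2"], rel=5e-3)
            assert fit.params.rho == pytest.approx(ref["rho"], rel=5e-3)
            assert fit.params.sigma2 == pytest.approx(ref["sigma2"], abs=5e-3)
            assert fit.beta[1] == pytest.approx(ref["beta1"], abs=5e-4)
            # plug-in GLS covariance, before small-sample adjustment
            assert np.sqrt(fit.beta_cov[1, 1]) == pytest.approx(ref["se"], rel=2e-3)

    def test_loglik_ml_internally_consistent(self, rng):
        y, design, D = _sim_spatial(rng)
        fit = fit_spatial(y, design, D, rng=0)
        again = marginal_loglik(y, design, fit.params, D, fit.beta)
        assert fit.loglik_ml == pytest.approx(again, abs=1e-8)
        assert fit.aic == pytest.approx(2 * 5 - 2 * fit.loglik_ml, abs=1e-9)

    def test_ml_nesting_never_below_nonspatial(self, rng):
        for tau2 in (0.0, 1.0):
            for rep in range(3):
                y, design, D = _sim_spatial(rng, tau2=tau2)
                sp = fit_spatial(y, design, D, objective="ml", rng=rep)
                ns = fit_nonspatial(y, design)
                assert sp.loglik_ml >= ns.loglik_ml - 1e-6

    def test_iid_data_collapses_to_nonspatial(self, rng):
        # pure nugget truth: the fitted spatial signal at the lattice spacing
        # vanishes and the AIC gap approaches the 2 x 2 extra-parameter
        # penalty. (tau2 itself is unidentifiable when rho collapses below
        # the spacing, so the effective nearest-neighbour correlation
        # h * exp(-d_min / rho) is the meaningful measure of spatial signal.)
        gaps, nn_corr = [], []
        for rep in range(12):
            y, design, D = _sim_spatial(rng, tau2=0.0, sigma2=1.0)
            sp = fit_spatial(y, design, D, objective="ml", rng=rep)
            ns = fit_nonspatial(y, design)
            h = sp.params.tau2 / (sp.params.tau2 + sp.params.sigma2)
            nn_corr.append(h * np.exp(-1.0 / sp.params.rho))
            gaps.append(sp.aic - ns.aic)
        assert np.median(nn_corr) < 0.05
        assert np.median(gaps) == pytest.approx(4.0, abs=0.25)

    def test_scale_equivariance(self, rng):
        y, design, D = _sim_spatial(rng)
        c = 3.7
        f1 = fit_spatial(y, design, D, rng=0)
        f2 = fit_spatial(c * y, design, D, rng=0)
        assert f2.params.tau2 == pytest.approx(c**2 * f1.params.tau2, rel=1e-3)
        # sigma2 sits on the 0 boundary here, so compare on the scale of the
        # total variance rather than relatively
        total2 = c**2 * (f1.params.tau2 + f1.params.sigma2)
        assert abs(f2.params.sigma2 - c**2 * f1.params.sigma2) < 1e-4 * total2
        assert f2.params.rho == pytest.approx(f1.params.rho, rel=1e-3)
        # df comes from finite differences of the information, so the
        # p-values agree to optimizer precision, not machine precision
        p1, p2 = wald_test(f1).p_value, wald_test(f2).p_value
        assert p2 == pytest.approx(p1, abs=5e-3)

    def test_translation_invariance(self, rng):
        coords = make_layout("squaregrid", 7, 7)
        D = squareform(pdist(coords))
        D2 = squareform(pdist(coords + np.array([250.0, -31.0])))
        n = 49
        ind = (coords[:, 0] < 3.5).astype(float)
        design = DesignSpec(ind)
        y = rng.normal(0, 1, n) + coords[:, 1] * 0.1
        f1 = fit_spatial(y, design, D, rng=0)
        f2 = fit_spatial(y, design, D2, rng=0)
        assert f1.loglik_ml == pytest.approx(f2.loglik_ml, abs=1e-6)
        assert f1.params.rho == pytest.approx(f2.params.rho, rel=1e-6)

    def test_too_few_units_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            y = rng.normal(0, 1, 4)
            ind = np.array([1.0, 1, 0, 0])
            fit_spatial(y, DesignSpec(ind), np.zeros((4, 4)) + 1 - np.eye(4))


class TestWald:
    def test_zero_estimate_gives_p_one(self):
        y = np.array([1.0, 2, 1, 2, 1.5, 1.5])
        ind = np.array([1.0, 1, 1, 0, 0, 0])
        fit = fit_nonspatial(y, DesignSpec(ind))
        fit.beta[1] = 0.0
        w = wald_test(fit)
        assert w.statistic == 0.0 and w.p_value == 1.0

    def test_large_n_spatial_reference_approaches_normal(self):
        from stlmm.spatial_lmm import FitResult

        fit = FitResult(
            beta=np.array([0.0, 1.959964]),
            beta_cov=np.array([[1.0, 0.0], [0.0, 1.0]]),
            sigma2=1.0,
            loglik_ml=0.0,
            aic=10.0,
            k_params=5,
            converged=True,
            n=200_000,
            spatial=True,
        )
        assert wald_test(fit).p_value == pytest.approx(0.05, abs=1e-4)

    def test_nonconverged_fit_rejected(self):
        from stlmm.spatial_lmm import FitResult

        fit = FitResult(
            beta=np.full(2, np.nan), beta_cov=np.full((2, 2), np.nan), sigma2=np.nan,
            loglik_ml=np.nan, aic=np.nan, k_params=5, converged=False, n=10,
        )
        with pytest.raises(ValueError):
            wald_test(fit)
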