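"""ECM estimator: E-step posteriors, CM closed forms, ascent, recovery."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.optimize import minimize

import bvsim
from bvsim.ecm import (
    FitConfig,
    _EStepCache,
    _fit_fixed_k,
    _lmm_init,
    cm_update_beta,
    cm_update_gamma,
    cm_update_omega,
    cm_update_sigma,
    cm_update_theta,
    e_step,
    fit,
    initialize,
    q1_value,
    q2_value,
    replace_params,
)
from bvsim.model import ClusteredBivariateData, compute_mu, subject_scatter
from bvsim.splines import bspline_design


@pytest.fixture(scope="module")
def estep_setup():
    """Small instance with a populated E-step cache at non-trivial params."""
    data, _ = bvsim.generate_sim1(10, seed=31)
    params, b1s, b2s = initialize(data, FitConfig(init="ols"), n_interior=2)
    params = replace_params(
        params, gamma=np.array([0.7, -0.3]),
        Sigma=np.array([[1.3, 0.4], [0.4, 1.1]]),
    )
    mu, B1, B2 = compute_mu(params, data, b1s, b2s)
    cache = _EStepCache(params, data, mu)
    return data, params, b1s, b2s, B1, B2, cache


class TestInitialize:
    def test_prescribed_starting_values(self, small_data):
        data, _ = small_data
        params, _, _ = initialize(data, FitConfig(init="ols"), n_interior=2)
        np.testing.assert_allclose(params.gamma, 0.0)
        np.testing.assert_allclose(params.Sigma, np.eye(2))
        assert np.linalg.norm(params.beta1) == pytest.approx(1.0, abs=1e-10)
        assert params.beta1[0] > 0 and params.beta2[0] > 0

    def test_linear_special_case_recovers_direction(self, rng):
        # y1 exactly linear in the index, additive noise only
        n, m = 40, 4
        N = n * m
        beta = np.array([2.0, 1.0, -1.0]) / np.sqrt(6.0)
        x1 = rng.uniform(size=(N, 3))
        x2 = rng.uniform(size=(N, 3))
        y1 = 3.0 * (x1 @ beta) + 0.01 * rng.standard_normal(N)
        y2 = 2.0 * (x2 @ beta) + 0.01 * rng.standard_normal(N)
        data = ClusteredBivariateData(
            subject_ids=np.arange(n), cluster_sizes=np.full(n, m),
            y=np.column_stack([y1, y2]), x1=x1, x2=x2,
            z1=np.ones((N, 1)), z2=np.ones((N, 1)),
        )
        params, _, _ = initialize(data, FitConfig(init="ols"), n_interior=1)
        assert np.abs(params.beta1 @ beta) > 0.999

    def test_theta_reproduces_normal_equations(self, small_data):
        data, _ = small_data
        params, b1s, b2s = initialize(data, FitConfig(init="ols"), n_interior=2)
        B1 = bspline_design(data.x1 @ params.beta1, b1s)
        ref = np.linalg.solve(B1.T @ B1, B1.T @ data.y[:, 0])
        np.testing.assert_allclose(params.theta1, ref, atol=1e-8)

    def test_lmm_initialization_runs(self, small_data):
        data, _ = small_data
        params, _, _ = initialize(data, FitConfig(init="lmm"), n_interior=2)
        assert np.linalg.eigvalsh(params.Omega)[0] > 0


class TestEStep:
    def test_posterior_moment_inequality(self, estep_setup):
        data, params, b1s, b2s, *_ , cache = estep_setup
        assert np.all(cache.c > 0) and np.all(cache.d > 0)
        assert np.all(cache.c * cache.d >= 1.0 - 1e-9)

    def test_state_fields_shapes(self, estep_setup):
        data, params, b1s, b2s, *_ = estep_setup
        state = e_step(params, data, b1s, b2s)
        D = data.z1.shape[1] + data.z2.shape[1]
        assert state.delta.shape == (data.n_subjects, D, D)
        assert state.r1.shape == (data.n_subjects, D)
        # Delta_i symmetric p.d.
        for i in range(data.n_subjects):
            np.testing.assert_allclose(state.delta[i], state.delta[i].T, atol=1e-10)
            assert np.linalg.eigvalsh(state.delta[i])[0] > 0

    def test_diffuse_omega_limit(self, estep_setup):
        data, params, b1s, b2s, *_ = estep_setup
        p = replace_params(params, Omega=1e8 * np.eye(4))
        state = e_step(p, data, b1s, b2s)
        Sigma_inv = np.linalg.inv(p.Sigma)
        for i in (0, 3):
            rows = data.subject_rows(i)
            A = np.zeros((4, 4))
            for j in range(rows.start, rows.stop):
                Zij = np.zeros((4, 2))
                Zij[:2, 0] = data.z1[j]
                Zij[2:, 1] = data.z2[j]
                A += Zij @ Sigma_inv @ Zij.T
            np.testing.assert_allclose(state.delta[i], np.linalg.inv(A), rtol=1e-4)

    def test_mixing_posterior_matches_quadrature(self):
        # single subject, one member, no random-effect slopes: E[V|y] and
        # E[1/V|y] from the hierarchical density by direct quadrature
        rng = np.random.default_rng(2)
        data = ClusteredBivariateData(
            subject_ids=[0, 1], cluster_sizes=[1, 1],
            y=rng.standard_normal((2, 2)) * 2,
            x1=rng.uniform(size=(2, 3)), x2=rng.uniform(size=(2, 3)),
            z1=np.ones((2, 1)), z2=np.ones((2, 1)),
        )
        # constant (order-1) spline bases so the 2-point fit does not
        # interpolate and the residuals stay away from zero
        params, b1s, b2s = initialize(
            data, FitConfig(init="ols", spline_order=1), n_interior=0)
        params = replace_params(params, gamma=np.array([0.5, 0.2]),
                                Omega=0.5 * np.eye(2))
        state = e_step(params, data, b1s, b2s)
        mu, _, _ = compute_mu(params, data, b1s, b2s)
        for i in range(2):
            G = subject_scatter(params, data, i)
            yi = data.y[i] - mu[i]
            f = lambda v: stats.multivariate_normal.pdf(
                yi, mean=v * params.gamma, cov=v * G) * np.exp(-v)
            den = integrate.quad(f, 0, np.inf, limit=400)[0]
            ev = integrate.quad(lambda v: v * f(v), 0, np.inf, limit=400)[0] / den
            evinv = integrate.quad(lambda v: f(v) / v, 0, np.inf, limit=400)[0] / den
            assert state.c[i] == pytest.approx(ev, rel=1e-6)
            assert state.d[i] == pytest.approx(evinv, rel=1e-6)


class TestCMClosedForms:
    """Each CM update must match a numerical maximizer of its Q block."""

    def test_theta(self, estep_setup):
        data, params, b1s, b2s, B1, B2, cache = estep_setup
        th1, th2 = cm_update_theta(cache, data, B1, B2, params.gamma, params.Sigma)
        K1 = B1.shape[1]
        x0 = np.concatenate([th1, th2])
        f = lambda th: -q1_value(th[:K1], th[K1:], params.gamma, params.Sigma,
                                 B1, B2, data, cache)
        res = minimize(f, x0 + 0.1, method="BFGS", options=dict(gtol=1e-12))
        np.testing.assert_allclose(x0, res.x, atol=1e-5)

    def test_gamma(self, estep_setup):
        data, params, b1s, b2s, B1, B2, cache = estep_setup
        gam = cm_update_gamma(cache, data, B1, B2, params.theta1, params.theta2)
        f = lambda g: -q1_value(params.theta1, params.theta2, g, params.Sigma,
                                B1, B2, data, cache)
        res = minimize(f, gam + 0.5, method="BFGS", options=dict(gtol=1e-12))
        np.testing.assert_allclose(gam, res.x, atol=1e-6)

    def test_sigma(self, estep_setup):
        data, params, b1s, b2s, B1, B2, cache = estep_setup
        Sig = cm_update_sigma(cache, data, B1, B2, params.theta1, params.theta2,
                              params.gamma)

        def f(v):
            L = np.array([[np.exp(v[0]), 0.0], [v[1], np.exp(v[2])]])
            return -q1_value(params.theta1, params.theta2, params.gamma,
                             L @ L.T, B1, B2, data, cache)

        res = minimize(f, [0.0, 0.0, 0.0], method="Nelder-Mead",
                       options=dict(xatol=1e-9, fatol=1e-12, maxiter=4000))
        L = np.array([[np.exp(res.x[0]), 0.0], [res.x[1], np.exp(res.x[2])]])
        np.testing.assert_allclose(Sig, L @ L.T, atol=1e-5)

    def test_sigma_symmetric(self, estep_setup):
        data, params, b1s, b2s, B1, B2, cache = estep_setup
        Sig = cm_update_sigma(cache, data, B1, B2, params.theta1, params.theta2,
                              params.gamma)
        np.testing.assert_allclose(Sig, Sig.T, atol=1e-12)

    def test_omega(self, estep_setup):
        data, params, b1s, b2s, B1, B2, cache = estep_setup
        Om = cm_update_omega(cache)
        # local maximum of Q2: random symmetric perturbations only lower it
        q0 = q2_value(Om, cache)
        rng = np.random.default_rng(1)
        for scale in (1e-3, 1e-2, 0.1):
            for _ in range(8):
                P = rng.standard_normal(Om.shape)
                cand = Om + scale * (P + P.T)
                if np.linalg.eigvalsh(cand)[0] <= 0:
                    continue
                assert q2_value(cand, cache) <= q0 + 1e-10

    def test_omega_reduces_to_mean_delta(self, estep_setup):
        data, params, b1s, b2s, B1, B2, cache = estep_setup
        saved_r1, saved_r2, saved_M = cache.r1, cache.r2, cache.M
        try:
            cache.M = cache.stats.Delta.copy()   # R1 = R2 = 0 case
            Om = cm_update_omega(cache)
            np.testing.assert_allclose(Om, cache.stats.Delta.mean(axis=0), atol=1e-12)
        finally:
            cache.r1, cache.r2, cache.M = saved_r1, saved_r2, saved_M

    def test_theta_gaussian_degenerate_case(self, estep_setup):
        # d_i = 1, R = 0, gamma = 0: weighted least squares of y on the design
        data, params, b1s, b2s, B1, B2, cache = estep_setup
        import copy
        c2 = copy.copy(cache)
        c2.d_row = np.ones_like(cache.d_row)
        c2.zR1 = np.zeros_like(cache.zR1)
        c2.zR2 = np.zeros_like(cache.zR2)
        th1, th2 = cm_update_theta(c2, data, B1, B2, np.zeros(2), np.eye(2))
        ref1 = np.linalg.solve(B1.T @ B1, B1.T @ data.y[:, 0])
        ref2 = np.linalg.solve(B2.T @ B2, B2.T @ data.y[:, 1])
        np.testing.assert_allclose(th1, ref1, atol=1e-8)
        np.testing.assert_allclose(th2, ref2, atol=1e-8)

    def test_beta_newton_direction_matches_fd_gradient(self, estep_setup):
        data, params, b1s, b2s, B1, B2, cache = estep_setup
        from bvsim.model import full_beta
        p1 = data.p[0]
        bm = np.concatenate([params.beta1[1:], params.beta2[1:]])

        def q_of_bm(v):
            b1, _ = full_beta(v[: p1 - 1])
            b2, _ = full_beta(v[p1 - 1:])
            D1 = bspline_design(data.x1 @ b1, b1s)
            D2 = bspline_design(data.x2 @ b2, b2s)
            return q1_value(params.theta1, params.theta2, params.gamma,
                            params.Sigma, D1, D2, data, cache)

        h = 1e-6
        grad_fd = np.array([
            (q_of_bm(bm + h * e) - q_of_bm(bm - h * e)) / (2 * h)
            for e in np.eye(len(bm))
        ])
        # the update must move uphill along the finite-difference gradient
        b1n, b2n, _, _ = cm_update_beta(cache, data, params, b1s, b2s, 1, B1=B1, B2=B2)
        step = np.concatenate([b1n[1:], b2n[1:]]) - bm
        assert step @ grad_fd > 0

    def test_beta_update_increases_q1(self, estep_setup):
        data, params, b1s, b2s, B1, B2, cache = estep_setup
        q_before = q1_value(params.theta1, params.theta2, params.gamma,
                            params.Sigma, B1, B2, data, cache)
        b1n, b2n, B1n, B2n = cm_update_beta(cache, data, params, b1s, b2s, 5,
                                            B1=B1, B2=B2)
        q_after = q1_value(params.theta1, params.theta2, params.gamma,
                           params.Sigma, B1n, B2n, data, cache)
        assert q_after >= q_before - 1e-10

    def test_beta_fixed_point_at_stationarity(self, estep_setup):
        data, params, b1s, b2s, B1, B2, cache = estep_setup
        # iterate the update to (near) stationarity, then one more call must
        # leave beta essentially unchanged
        p = params
        for _ in range(20):
            b1n, b2n, _, _ = cm_update_beta(cache, data, p, b1s, b2s, 10)
            p = replace_params(p, beta1=b1n, beta2=b2n)
        b1f, b2f, _, _ = cm_update_beta(cache, data, p, b1s, b2s, 10)
        assert np.linalg.norm(b1f - p.beta1) < 1e-6
        assert np.linalg.norm(b2f - p.beta2) < 1e-6


class TestFit:
    @pytest.mark.parametrize("seed", range(6))
    def test_loglik_monotone_on_random_datasets(self, seed):
        data, _ = bvsim.generate_sim1(15, seed=100 + seed)
        cfg = FitConfig(max_iter=60, tol_param=1e-4, n_interior=2,
                        init="ols", newton_max=2)
        res = _fit_fixed_k(data, cfg, 2, init_core=_lmm_init(data, "ols"))
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-8)

    def test_subject_permutation_invariance(self, small_data, quick_config):
        data, _ = small_data
        res = _fit_fixed_k(data, quick_config, 2, init_core=_lmm_init(data, "ols"))
        perm = np.random.default_rng(5).permutation(data.n_subjects)
        pdata = data.subset_subjects(perm)
        pres = _fit_fixed_k(pdata, quick_config, 2, init_core=_lmm_init(pdata, "ols"))
        np.testing.assert_allclose(res.params.beta1, pres.params.beta1, atol=1e-8)
        np.testing.assert_allclose(res.params.gamma, pres.params.gamma, atol=1e-7)

    def test_parameter_recovery_sim1(self):
        data, truth = bvsim.generate_sim1(120, seed=77)
        cfg = FitConfig(max_iter=500, tol_param=1e-5, n_interior=2,
                        init="ols", newton_max=1)
        res = _fit_fixed_k(data, cfg, 2, init_core=_lmm_init(data, "ols"))
        assert np.linalg.norm(res.params.beta1 - truth.beta1) < 0.08
        assert np.linalg.norm(res.params.beta2 - truth.beta2) < 0.08
        assert np.linalg.norm(res.params.gamma - truth.gamma) < 1.2

    def test_auto_knot_selection_records_table(self, small_data):
        data, _ = small_data
        cfg = FitConfig(max_iter=40, tol_param=1e-3, init="ols",
                        newton_max=1, select_max_iter=10)
        res = fit(data, cfg)
        assert res.n_interior in res.sic_table
        assert res.sic_table[res.n_interior] == min(res.sic_table.values())

    def test_report_contains_estimates(self, small_fit):
        text = small_fit.report()
        assert "beta1" in text and "Sigma" in text and "log-likelihood" in text

    def test_predict_g_clamps_outside_support(self, small_fit):
        a, b = small_fit.basis1.support
        inside = small_fit.predict_g(1, np.array([a, b - 1e-9]))
        outside = small_fit.predict_g(1, np.array([a - 10.0, b + 10.0]))
        np.testing.assert_allclose(outside, inside, atol=1e-6)
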