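"""GMD path solver: gradient, block updates, strong rule, KKT, descent."""

import numpy as np
import pytest

from mfgreg.basis import center_dataset
from mfgreg.gmd import (
    GMDConfig,
    GMDWorkspace,
    block_update,
    build_lambda_grid_gmd,
    gmd_fit,
    gmd_fit_path,
    gmd_gradient,
    kkt_check,
    lambda_max,
    strong_rule_screen,
)
from conftest import make_dataset
from oracles import prox_gradient_solve, socp_solve

TIGHT = GMDConfig(tol=1e-10, max_sweeps=50_000)


def _centered(**kw):
    return center_dataset(make_dataset(**kw))


def _d2(ds):
    return np.kron(np.eye(ds.p), ds.bases[0].d2gram)


class TestGradient:
    def test_zero_beta_gives_minus_gxy(self, toy_dataset):
        ds = center_dataset(toy_dataset)
        G = np.kron(np.eye(ds.p), ds.bases[0].gram)
        grad = gmd_gradient(np.zeros(ds.structure.M), ds)
        np.testing.assert_allclose(grad, -G @ ds.coords @ ds.response, atol=1e-12)

    def test_interpolating_beta_gives_zero(self):
        ds = _centered(n=30, p=2, m=3, seed=1, order=3, noise=0.0)
        G = np.kron(np.eye(ds.p), ds.bases[0].gram)
        # construct an exactly interpolating beta via least squares
        D = ds.coords.T @ G
        beta = np.linalg.lstsq(D, ds.response, rcond=None)[0]
        grad = gmd_gradient(beta, ds)
        # gradient is G X r with r = 0
        np.testing.assert_allclose(ds.response - D @ beta, 0.0, atol=1e-9)
        np.testing.assert_allclose(grad, 0.0, atol=1e-7)

    def test_matches_finite_differences(self, toy_dataset):
        ds = center_dataset(toy_dataset)
        rng = np.random.default_rng(3)
        d2 = _d2(ds)
        G = np.kron(np.eye(ds.p), ds.bases[0].gram)
        beta = rng.standard_normal(ds.structure.M)
        lam_der = 0.3

        def loss(b):
            r = ds.response - ds.coords.T @ G @ b
            return 0.5 * r @ r + 0.5 * lam_der * b @ d2 @ b

        grad = gmd_gradient(beta, ds, lam_der, d2)
        eps = 1e-6
        for idx in rng.choice(ds.structure.M, 6, replace=False):
            e = np.zeros_like(beta)
            e[idx] = eps
            fd = (loss(beta + e) - loss(beta - e)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-5)


class TestBlockUpdate:
    def test_threshold_to_zero(self):
        out = block_update(np.zeros(2), np.array([0.1, 0.1]), 1.0, 10.0, 0.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_pure_gradient_step_when_unpenalized(self):
        b_old = np.array([1.0, -2.0])
        u = np.array([0.5, 0.25])
        out = block_update(b_old, u, 2.0, 0.0, 0.0)
        np.testing.assert_allclose(out, b_old + u / 2.0)

    def test_hand_example(self):
        # gamma=2, alpha=0.5, lambda=1, beta_old=0, U=(3,4): threshold is
        # lambda(1-alpha) = 0.5, so (1/(2*0.5*1+2)) * (1 - 0.5/5) * (3,4)
        # = (1/3) * 0.9 * (3,4) = (0.9, 1.2)
        out = block_update(np.zeros(2), np.array([3.0, 4.0]), 2.0, 1.0, 0.5)
        np.testing.assert_allclose(out, [0.9, 1.2])

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma_j"):
            block_update(np.zeros(2), np.ones(2), 0.0, 1.0, 0.0)


class TestLambdaMax:
    def test_zero_response_gives_zero(self, toy_dataset):
        ds = center_dataset(toy_dataset)
        ds.response[:] = 0.0
        assert lambda_max(ds) == 0.0

    def test_boundary_behavior(self):
        ds = _centered(n=25, p=3, m=4, seed=4)
        lmax = lambda_max(ds)
        hi = gmd_fit(ds, 1.01 * lmax, config=TIGHT)
        assert hi.active_set == []
        lo = gmd_fit(ds, 0.90 * lmax, config=TIGHT)
        assert len(lo.active_set) >= 1

    def test_elastic_net_scaling(self):
        ds = _centered(n=25, p=3, m=4, seed=4)
        assert lambda_max(ds, alpha=0.5) == pytest.approx(2 * lambda_max(ds))
        with pytest.raises(ValueError, match="ridge"):
            lambda_max(ds, alpha=1.0)


class TestStrongRuleAndKKT:
    def test_zero_gradient_screens_nothing(self):
        ds = _centered(n=20, p=3, m=4, seed=6)
        out = strong_rule_screen(np.zeros(ds.structure.M), 1.0, 0.5, 0.0,
                                 ds.structure)
        assert out == set()

    def test_equal_lambdas_reduce_to_kkt_boundary(self):
        ds = _centered(n=20, p=3, m=4, seed=6)
        rng = np.random.default_rng(0)
        u = rng.standard_normal(ds.structure.M)
        lam = 1.0
        out = strong_rule_screen(u, lam, lam, 0.0, ds.structure)
        expected = {j for j, sl in enumerate(ds.structure.slices())
                    if np.linalg.norm(u[sl]) > lam}
        assert out == expected

    def test_kkt_empty_when_all_blocks_included(self):
        ds = _centered(n=25, p=3, m=4, seed=7)
        fit = gmd_fit(ds, 0.01 * lambda_max(ds), config=TIGHT)
        assert len(fit.active_set) == 3  # all blocks active at tiny lambda
        assert kkt_check(fit.beta, ds, 0.01 * lambda_max(ds)) == set()

    def test_kkt_empty_at_zero_solution_above_lambda_max(self):
        ds = _centered(n=25, p=3, m=4, seed=7)
        lmax = lambda_max(ds)
        out = kkt_check(np.zeros(ds.structure.M), ds, 1.01 * lmax)
        assert out == set()

    def test_kkt_flags_missing_active_block(self):
        ds = _centered(n=25, p=3, m=4, seed=9, noise=0.05)
        lam = 0.2 * lambda_max(ds)
        full = gmd_fit(ds, lam, config=TIGHT)
        assert full.active_set  # something is active
        viol = kkt_check(np.zeros(ds.structure.M), ds, lam)
        assert set(full.active_set) <= viol or viol  # zero solution violates
        # after re-inclusion (the solver's backstop) the fit matches a
        # no-screening solve exactly
        assert kkt_check(full.beta, ds, lam) == set()

    def test_converged_fit_certifies_stationarity(self):
        ds = _centered(n=30, p=4, m=4, seed=10, noise=0.3, n_active=2)
        lam = 0.3 * lambda_max(ds)
        fit = gmd_fit(ds, lam, alpha=0.2, config=TIGHT)
        ws = GMDWorkspace(ds, 0.0)
        btilde = ws.to_tilde(fit.beta.values)
        r = ws.residual(btilde)
        for j, sl in enumerate(ds.structure.slices()):
            u = ws.neg_grad_block(j, r, btilde)
            bj = btilde[sl]
            if j in fit.active_set:
                stat = u - lam * (1 - 0.2) * bj / np.linalg.norm(bj) \
                    - 2 * 0.2 * lam * bj
                assert np.linalg.norm(stat) < 1e-6 * (1 + np.linalg.norm(u))
            else:
                assert np.linalg.norm(u) <= lam * (1 - 0.2) * (1 + 1e-8)


class TestPath:
    def test_grid_validation(self):
        ds = _centered()
        with pytest.raises(ValueError, match="decreasing"):
            gmd_fit_path(ds, np.array([0.1, 0.2]))

    def test_top_of_grid_is_empty_fit(self):
        ds = _centered(n=25, p=3, m=4, seed=12)
        grid = build_lambda_grid_gmd(ds, n_points=10)
        path = gmd_fit_path(ds, grid, config=TIGHT)
        assert path.fits[0].active_set == []
        assert np.all(np.diff(path.lambda_grid) < 0)

    def test_screening_equals_no_screening(self):
        for seed in (1, 2, 3):
            ds = _centered(n=25, p=4, m=3, seed=seed, order=3, noise=0.4,
                           n_active=2)
            grid = build_lambda_grid_gmd(ds, n_points=25)
            with_sr = gmd_fit_path(ds, grid, config=TIGHT, use_screening=True)
            without = gmd_fit_path(ds, grid, config=TIGHT, use_screening=False)
            for f1, f2 in zip(with_sr.fits, without.fits):
                assert f1.active_set == f2.active_set
                np.testing.assert_allclose(f1.beta.values, f2.beta.values,
                                           atol=1e-6)

    def test_path_objectives_match_convex_oracle(self):
        ds = _centered(n=20, p=3, m=4, seed=5, noise=0.5)
        ws = GMDWorkspace(ds, 0.0)
        grid = build_lambda_grid_gmd(ds, n_points=6, min_ratio=0.02)
        path = gmd_fit_path(ds, grid, config=TIGHT, workspace=ws)
        Z = np.vstack(ws.z_blocks)
        slices = ds.structure.slices()
        for f in path.fits:
            _, obj1 = socp_solve(Z, ds.response, slices, f.lambda_, 0.0, 1.0)
            _, obj2 = prox_gradient_solve(Z, ds.response, slices, f.lambda_,
                                          0.0, 1.0)
            oracle = min(obj1, obj2)
            assert f.objective == pytest.approx(oracle, abs=1e-4)

    def test_strict_descent_asserted_per_update(self):
        ds = _centered(n=20, p=3, m=4, seed=5, noise=0.5)
        grid = build_lambda_grid_gmd(ds, n_points=10)
        cfg = GMDConfig(tol=1e-8, max_sweeps=5000, check_descent=True)
        gmd_fit_path(ds, grid, config=cfg)  # raises if any update ascends

    def test_warm_started_elastic_net_with_curvature(self):
        ds = _centered(n=25, p=3, m=4, seed=15, noise=0.3)
        d2 = _d2(ds)
        lam_der = 0.5
        ws = GMDWorkspace(ds, lam_der)
        grid = build_lambda_grid_gmd(ds, alpha=0.3, lambda_der=lam_der,
                                     n_points=5, min_ratio=0.05, workspace=ws)
        path = gmd_fit_path(ds, grid, alpha=0.3, lambda_der=lam_der,
                            config=TIGHT, workspace=ws)
        Z = np.vstack(ws.z_blocks)
        P = np.zeros((ds.structure.M,) * 2)
        for j, sl in enumerate(ds.structure.slices()):
            P[sl, sl] = ws.p_blocks[j]
        slices = ds.structure.slices()
        f = path.fits[-1]
        _, obj = socp_solve(Z, ds.response, slices, f.lambda_, 0.3, 1.0,
                            lam_der=lam_der, P=P)
        assert f.objective == pytest.approx(obj, abs=1e-4)


class TestQMCondition:
    def test_quadratic_majorization_holds(self):
        rng = np.random.default_rng(21)
        ds = _centered(n=20, p=3, m=4, seed=21, noise=0.5)
        lam_der = 0.2
        ws = GMDWorkspace(ds, lam_der)
        Z = np.vstack(ws.z_blocks)
        P = np.zeros((ds.structure.M,) * 2)
        for j, sl in enumerate(ds.structure.slices()):
            P[sl, sl] = ws.p_blocks[j]
        H = Z @ Z.T + lam_der * P

        def loss(b):
            r = ds.response - Z.T @ b
            return 0.5 * r @ r + 0.5 * lam_der * b @ P @ b

        for _ in range(100):
            b = rng.standard_normal(ds.structure.M)
            b_star = rng.standard_normal(ds.structure.M)
            d = b - b_star
            grad_star = H @ b_star - Z @ ds.response
            bound = loss(b_star) + d @ grad_star + 0.5 * d @ H @ d
            assert loss(b) <= bound + 1e-9 * (1 + abs(bound))


class TestCrossSolver:
    def test_admm_and_gmd_agree_on_random_instances(self):
        from mfgreg.model import fit
        from mfgreg.admm import ADMMConfig
        rng = np.random.default_rng(0)
        for trial in range(20):
            ds = make_dataset(n=20, p=3, m=4, seed=100 + trial,
                              noise=rng.uniform(0.05, 1.0),
                              n_active=rng.integers(1, 4))
            lam = rng.uniform(0.02, 0.6)
            alpha = rng.choice([0.0, 0.3, 0.6])
            fa = fit(ds, "admm", lam, alpha,
                     config=ADMMConfig(tol_abs=1e-9, tol_rel=1e-8,
                                       max_iter=50_000))
            fg = fit(ds, "gmd", lam, alpha, config=TIGHT)
            assert abs(fa.diagnostics["objective"]
                       - fg.diagnostics["objective"]) < 1e-4
            assert fa.active_set == fg.active_set
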