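"""Basis construction, Gram matrices, projection, centering, inner products."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfgreg.basis import (
    BlockStructure,
    CoordinateVector,
    FunctionalDataset,
    build_basis,
    build_custom_basis,
    center_dataset,
    empirical_covariance_coords,
    inner_product,
    project_curve,
)
from oracles import riemann_gram


class TestBuildBasis:
    def test_fourier_gram_is_identity(self, fourier_basis):
        # orthonormal system on its period
        np.testing.assert_allclose(fourier_basis.gram, np.eye(5), atol=1e-10)

    def test_fourier_m3_gram_identity(self):
        b = build_basis("fourier", 3, (0, 1))
        np.testing.assert_allclose(b.gram, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("kind,m,order", [("bspline", 4, 4), ("bspline", 6, 4),
                                              ("bspline", 8, 3)])
    def test_bspline_gram_matches_riemann_oracle(self, kind, m, order):
        b = build_basis(kind, m, (0.0, 1.0), order=order)
        np.testing.assert_allclose(b.gram, riemann_gram(b), atol=1e-8)

    def test_bspline_d2gram_matches_riemann_oracle(self, cubic_basis):
        np.testing.assert_allclose(cubic_basis.d2gram,
                                   riemann_gram(cubic_basis, deriv=2),
                                   atol=1e-5)

    def test_fourier_d2gram_matches_riemann_oracle(self, fourier_basis):
        np.testing.assert_allclose(fourier_basis.d2gram,
                                   riemann_gram(fourier_basis, deriv=2),
                                   rtol=1e-6, atol=1e-6)

    def test_piecewise_linear_d2gram_is_zero(self):
        b = build_basis("bspline", 4, (0, 1), order=2)
        assert np.all(b.d2gram == 0.0)

    def test_gram_symmetric_positive_definite(self, cubic_basis, fourier_basis):
        for b in (cubic_basis, fourier_basis):
            np.testing.assert_allclose(b.gram, b.gram.T, atol=1e-12)
            assert np.linalg.eigvalsh(b.gram)[0] > 1e-10 * np.linalg.eigvalsh(b.gram)[-1]
            assert np.linalg.eigvalsh(b.d2gram)[0] > -1e-8

    def test_domain_in_original_units(self):
        b = build_basis("bspline", 5, (2.0, 6.0), order=4)
        # constant function representable: sum of B-splines = 1, integral = 4
        ones = np.ones(5)
        assert ones @ b.gram @ ones == pytest.approx(4.0, abs=1e-8)

    @pytest.mark.parametrize("kind,m,order,err", [
        ("bspline", 3, 4, "m >="), ("fourier", 4, None, "odd"),
        ("bspline", 4, 0, "order"), ("nope", 5, 4, "kind"),
    ])
    def test_invalid_parameters(self, kind, m, order, err):
        with pytest.raises(ValueError, match=err):
            if order is None:
                build_basis(kind, m, (0, 1))
            else:
                build_basis(kind, m, (0, 1), order=order)

    def test_degenerate_domain(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_basis("bspline", 5, (1.0, 1.0))

    def test_evaluation_finite_on_domain(self, cubic_basis):
        t = np.linspace(0, 1, 57)
        assert np.all(np.isfinite(cubic_basis.evaluate(t)))
        with pytest.raises(ValueError, match="outside"):
            cubic_basis.evaluate([1.5])


class TestCustomBasisGrams:
    def test_constant_basis_on_0_2(self):
        b = build_custom_basis([lambda t: np.ones_like(t)], (0, 2),
                               d2funcs=[lambda t: np.zeros_like(t)])
        np.testing.assert_allclose(b.gram, [[2.0]], atol=1e-10)

    def test_monomial_1_t_zero_d2gram(self):
        b = build_custom_basis(
            [lambda t: np.ones_like(t), lambda t: t], (0, 1),
            d2funcs=[lambda t: np.zeros_like(t)] * 2)
        np.testing.assert_allclose(b.d2gram, np.zeros((2, 2)), atol=1e-12)

    def test_t_squared_d2gram(self):
        b = build_custom_basis([lambda t: t ** 2], (0, 1),
                               d2funcs=[lambda t: 2 * np.ones_like(t)])
        np.testing.assert_allclose(b.d2gram, [[4.0]], atol=1e-10)


class TestProjectCurve:
    def test_span_member_recovery(self, fourier_basis):
        t = np.linspace(0, 1, 100)
        vals = fourier_basis.evaluate(t)[:, 2]  # b_2 sampled
        coef = project_curve(t, vals, fourier_basis)
        np.testing.assert_allclose(coef, np.eye(5)[2], atol=1e-10)

    def test_zero_curve(self, cubic_basis):
        t = np.linspace(0, 1, 50)
        np.testing.assert_allclose(project_curve(t, np.zeros(50), cubic_basis),
                                   np.zeros(6), atol=1e-14)

    def test_noisy_sine_matches_normal_equations(self, fourier_basis):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 1, 100)
        noise = 0.05 * rng.standard_normal(100)
        vals = np.sin(2 * np.pi * t) + noise
        coef = project_curve(t, vals, fourier_basis)
        E = fourier_basis.evaluate(t)
        oracle = np.linalg.solve(E.T @ E, E.T @ vals)
        np.testing.assert_allclose(coef, oracle, atol=1e-10)
        resid = vals - E @ coef
        assert np.mean(resid ** 2) <= 1.1 * np.var(noise) + 1e-4
        # sin(2 pi t) coefficient dominates
        assert np.argmax(np.abs(coef)) == 1

    def test_rank_deficiency_error(self, cubic_basis):
        with pytest.raises(ValueError, match="rank-deficient"):
            project_curve([0.1, 0.5, 0.9], [1, 2, 3], cubic_basis)

    def test_times_outside_domain_error(self, cubic_basis):
        t = np.linspace(-0.2, 1.0, 20)
        with pytest.raises(ValueError, match="outside"):
            project_curve(t, np.ones(20), cubic_basis)


class TestCentering:
    def test_idempotent_and_row_sums(self, toy_dataset):
        c1 = center_dataset(toy_dataset)
        c2 = center_dataset(c1)
        np.testing.assert_allclose(c1.coords, c2.coords)
        assert np.abs(c1.coords.sum(axis=1)).max() < 1e-8 * toy_dataset.n
        assert abs(c1.response.sum()) < 1e-8 * toy_dataset.n

    def test_matches_naive_loop_oracle(self, toy_dataset):
        c = center_dataset(toy_dataset)
        expected = np.empty_like(toy_dataset.coords)
        for r in range(toy_dataset.coords.shape[0]):
            expected[r] = toy_dataset.coords[r] - toy_dataset.coords[r].mean()
        np.testing.assert_allclose(c.coords, expected, atol=1e-12)

    def test_n_below_two_rejected(self, cubic_basis):
        ds = FunctionalDataset(bases=[cubic_basis], coords=np.ones((6, 1)),
                               response=[1.0])
        with pytest.raises(ValueError, match="n >= 2"):
            center_dataset(ds)


class TestInnerProduct:
    def _vec(self, values, struct, tag="B"):
        return CoordinateVector(np.asarray(values, float), struct, tag=tag)

    def test_zero_and_orthonormal_tag_c(self):
        s = BlockStructure((2, 2))
        z = self._vec(np.zeros(4), s, "C")
        assert inner_product(z, z) == 0.0
        e1 = self._vec([1, 0, 0, 0], s, "C")
        e2 = self._vec([0, 1, 0, 0], s, "C")
        assert inner_product(e1, e2) == 0.0

    def test_tag_b_matches_riemann_reconstruction(self, cubic_basis):
        rng = np.random.default_rng(5)
        ds = FunctionalDataset(bases=[cubic_basis, cubic_basis],
                               coords=rng.standard_normal((12, 3)),
                               response=np.zeros(3))
        s = ds.structure
        f = self._vec(rng.standard_normal(12), s)
        g = self._vec(rng.standard_normal(12), s)
        t = np.linspace(0, 1, 100_001)
        E = cubic_basis.evaluate(t)
        oracle = sum(np.trapezoid((E @ f.values[sl]) * (E @ g.values[sl]), t)
                     for sl in s.slices())
        assert inner_product(f, g, ds) == pytest.approx(oracle, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bilinear_symmetric_nonnegative(self, cubic_basis, seed):
        rng = np.random.default_rng(seed)
        bases = [cubic_basis, cubic_basis]
        s = BlockStructure((6, 6))
        f = self._vec(rng.standard_normal(12), s)
        g = self._vec(rng.standard_normal(12), s)
        h = self._vec(rng.standard_normal(12), s)
        a = rng.standard_normal()
        ip = lambda x, z: inner_product(x, z, bases=bases)
        assert ip(f, g) == pytest.approx(ip(g, f), rel=1e-10, abs=1e-12)
        lhs = ip(self._vec(a * f.values + h.values, s), g)
        assert lhs == pytest.approx(a * ip(f, g) + ip(h, g), rel=1e-9, abs=1e-9)
        assert ip(f, f) >= 0.0

    def test_mismatched_structure_rejected(self):
        f = self._vec([1, 2], BlockStructure((2,)), "C")
        g = self._vec([1, 2, 3], BlockStructure((3,)), "C")
        with pytest.raises(ValueError, match="mismatch"):
            inner_product(f, g)


class TestEmpiricalCovariance:
    def test_constant_curves_give_zero(self, cubic_basis):
        ds = FunctionalDataset(bases=[cubic_basis],
                               coords=np.tile([[1.], [2.], [0.], [1.], [3.], [1.]], 4),
                               response=np.zeros(4))
        gxx, gyx = empirical_covariance_coords(ds)
        np.testing.assert_allclose(gxx, 0.0, atol=1e-12)
        np.testing.assert_allclose(gyx, 0.0, atol=1e-12)

    def test_two_point_hand_example(self):
        basis = build_custom_basis([lambda t: np.ones_like(t)], (0, 1))
        ds = FunctionalDataset(bases=[basis], coords=np.array([[1.0, -1.0]]),
                               response=np.zeros(2))
        gxx, _ = empirical_covariance_coords(ds)
        np.testing.assert_allclose(gxx, [[1.0]], atol=1e-12)

    def test_matches_explicit_loop_oracle(self, toy_dataset):
        ds = center_dataset(toy_dataset)
        G = np.kron(np.eye(ds.p), ds.bases[0].gram)
        expected = sum(np.outer(ds.coords[:, i], ds.coords[:, i]) @ G
                       for i in range(ds.n)) / ds.n
        gxx, gyx = empirical_covariance_coords(toy_dataset)
        np.testing.assert_allclose(gxx, expected, atol=1e-10)
        expected_yx = sum(ds.response[i] * ds.coords[:, i] for i in range(ds.n)) @ G / ds.n
        np.testing.assert_allclose(gyx, expected_yx, atol=1e-10)
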