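import numpy as np
import pytest
from scipy.stats import multivariate_normal

from dyngp.kernels import KernelSpec, add_jitter, eval_kernel
from dyngp.sparse_gp import (
    DonorDesign,
    LowRankCovariance,
    VarianceComponents,
    build_factors,
    lowrank_solve,
    rank_update_quad_logdet,
    titsias_bound,
)


def dense_penalized_loglik(y, cov, pen):
    n = len(y)
    return multivariate_normal.logpdf(y, np.zeros(n), cov) - pen


class TestBuildFactors:
    def test_inducing_at_data_gives_zero_ktilde(self, rng):
        X = rng.normal(size=(12, 1))
        spec = KernelSpec("ardse", variance=2.0, lengthscales=np.array([0.8]))
        f = build_factors(spec, X, X)
        assert np.max(np.abs(f.ktilde_diag)) <= 1e-6 * spec.variance

    def test_single_inducing_point_closed_form(self, rng):
        X = rng.normal(size=(10, 1))
        t1 = np.array([[0.2]])
        spec = KernelSpec("ardse", variance=1.5, lengthscales=np.array([1.1]))
        f = build_factors(spec, X, t1)
        k_xt = eval_kernel(spec, X, t1)[:, 0]
        k_tt = eval_kernel(spec, t1, t1)[0, 0]
        expected = np.clip(1.5 - k_xt**2 / (k_tt + 1e-6 * k_tt), 0, None)
        assert np.allclose(f.ktilde_diag, expected, atol=1e-5)

    def test_nystrom_reconstruction_matches_dense(self, rng):
        X = rng.normal(size=(20, 2))
        T = rng.normal(size=(5, 2))
        spec = KernelSpec("ardse", variance=0.9, lengthscales=np.array([0.7, 1.3]))
        f = build_factors(spec, X, T)
        kmm = f.chol_kmm @ f.chol_kmm.T
        dense = f.knm @ np.linalg.solve(kmm, f.knm.T)
        assert np.allclose(f.phi @ f.phi.T, dense, rtol=1e-8, atol=1e-10)
        assert np.allclose(f.C @ kmm, f.knm, rtol=1e-8, atol=1e-10)

    def test_too_many_inducing_points_rejected(self, rng):
        spec = KernelSpec("ardse", lengthscales=np.array([1.0]))
        with pytest.raises(ValueError):
            build_factors(spec, rng.normal(size=(3, 1)), rng.normal(size=(5, 1)))


class TestTitsiasBound:
    def test_h1_reduces_to_h0_at_zero_delta_d(self, small_instance):
        si = small_instance
        vc = VarianceComponents(0.8, delta_d=0.0)
        b0 = titsias_bound(si["y"], si["factors"], vc, hypothesis="H0")
        b1 = titsias_bound(si["y"], si["factors"], vc, si["donor"], hypothesis="H1")
        assert b1 == pytest.approx(b0, rel=1e-12)

    def test_h2_reduces_to_h1_at_zero_delta_g(self, small_instance):
        si = small_instance
        vc = VarianceComponents(0.8, delta_d=0.4, delta_g=0.0)
        b1 = titsias_bound(si["y"], si["factors"], vc, si["donor"], hypothesis="H1")
        b2 = titsias_bound(si["y"], si["factors"], vc, si["donor"], si["g"], "H2")
        assert b2 == pytest.approx(b1, rel=1e-12)

    def test_all_three_bounds_match_dense_oracle(self, small_instance):
        si = small_instance
        n = si["n"]
        y, g, Z = si["y"], si["g"], si["donor"].Z
        f = si["factors"]
        s2, dd, dg = 0.8, 0.4, 0.25
        vc = VarianceComponents(s2, dd, dg)
        P = f.phi @ f.phi.T
        kt = f.ktilde_diag
        G = np.diag(g)
        V = s2 * np.eye(n) + P
        Vd = V + dd * P * (Z @ Z.T)
        Vg = Vd + dg * G @ P @ G
        assert titsias_bound(y, f, vc, hypothesis="H0") == pytest.approx(
            dense_penalized_loglik(y, V, kt.sum() / (2 * s2)), rel=1e-8)
        assert titsias_bound(y, f, vc, si["donor"], hypothesis="H1") == pytest.approx(
            dense_penalized_loglik(y, Vd, (1 + dd) * kt.sum() / (2 * s2)), rel=1e-8)
        pen2 = ((1 + dd) * kt.sum() + dg * np.sum(g * g * kt)) / (2 * s2)
        assert titsias_bound(y, f, vc, si["donor"], g, "H2") == pytest.approx(
            dense_penalized_loglik(y, Vg, pen2), rel=1e-8)

    def test_bound_equals_exact_marginal_at_full_inducing(self, rng):
        n = 14
        X = rng.normal(size=(n, 1))
        spec = KernelSpec("ardse", variance=1.2, lengthscales=np.array([0.9]))
        y = rng.normal(size=n)
        s2 = 0.6
        b = titsias_bound(y, build_factors(spec, X, X),
                          VarianceComponents(s2), hypothesis="H0")
        exact = multivariate_normal.logpdf(
            y, np.zeros(n), s2 * np.eye(n) + eval_kernel(spec, X, X))
        assert b == pytest.approx(exact, rel=1e-6)

    def test_bound_dominated_by_exact_marginal(self, rng):
        """L2^{H0} <= exact log marginal for any inducing set."""
        n = 16
        X = rng.normal(size=(n, 1))
        spec = KernelSpec("ardse", variance=1.0, lengthscales=np.array([0.5]))
        y = rng.normal(size=n)
        s2 = 0.7
        exact = multivariate_normal.logpdf(
            y, np.zeros(n), s2 * np.eye(n) + eval_kernel(spec, X, X))
        for m in [1, 3, 8, n]:
            b = titsias_bound(y, build_factors(spec, X, X[:m]),
                              VarianceComponents(s2), hypothesis="H0")
            assert b <= exact + 1e-7 * abs(exact)


class TestLowRankSolve:
    def test_matches_dense_inverse(self, rng):
        n, m, n_d = 12, 3, 3
        X = rng.normal(size=(n, 1))
        T = rng.normal(size=(m, 1))
        spec = KernelSpec("ardse", variance=1.0, lengthscales=np.array([1.0]))
        f = build_factors(spec, X, T)
        donor = DonorDesign.from_assignment(rng.integers(0, n_d, size=n))
        vc = VarianceComponents(0.5, delta_d=0.7)
        P = f.phi @ f.phi.T
        Vd = 0.5 * np.eye(n) + P + 0.7 * P * (donor.Z @ donor.Z.T)
        rhs = rng.normal(size=(n, 4))
        assert np.allclose(lowrank_solve(f, donor, vc, rhs),
                           np.linalg.solve(Vd, rhs), rtol=1e-8, atol=1e-10)

    def test_delta_zero_reduces_to_plain_woodbury(self, small_instance, rng):
        si = small_instance
        vc = VarianceComponents(0.9, delta_d=0.0)
        rhs = rng.normal(size=si["n"])
        plain = LowRankCovariance(0.9, si["factors"].phi).solve(rhs)
        assert np.allclose(lowrank_solve(si["factors"], si["donor"], vc, rhs),
                           plain, rtol=1e-10)

    def test_single_donor_hadamard_with_ones(self, rng):
        n, m = 10, 3
        X = rng.normal(size=(n, 1))
        spec = KernelSpec("ardse", lengthscales=np.array([0.8]))
        f = build_factors(spec, X, rng.normal(size=(m, 1)))
        donor = DonorDesign.from_assignment(np.zeros(n, dtype=int))
        dd = 0.6
        P = f.phi @ f.phi.T
        Vd = 0.4 * np.eye(n) + (1 + dd) * P
        rhs = rng.normal(size=n)
        out = lowrank_solve(f, donor, VarianceComponents(0.4, dd), rhs)
        assert np.allclose(out, np.linalg.solve(Vd, rhs), rtol=1e-8)

    def test_general_kinship_low_rank_path(self, rng):
        n, m = 14, 4
        X = rng.normal(size=(n, 1))
        spec = KernelSpec("ardse", lengthscales=np.array([1.0]))
        f = build_factors(spec, X, rng.normal(size=(m, 1)))
        A = rng.normal(size=(n, n))
        R = A @ A.T / n
        donor = DonorDesign.from_kinship(R)
        Rhat = donor.Z @ donor.Z.T
        assert np.linalg.norm(Rhat - R) <= 0.01 * np.linalg.norm(R)
        P = f.phi @ f.phi.T
        Vd = 0.5 * np.eye(n) + P + 0.3 * P * Rhat
        rhs = rng.normal(size=n)
        out = lowrank_solve(f, donor, VarianceComponents(0.5, 0.3), rhs)
        assert np.allclose(out, np.linalg.solve(Vd, rhs), rtol=1e-8)

    def test_logdet_consistency(self, small_instance):
        si = small_instance
        cov = LowRankCovariance(0.7, si["factors"].phi, si["donor"], 0.5)
        P = si["factors"].phi @ si["factors"].phi.T
        Z = si["donor"].Z
        Vd = 0.7 * np.eye(si["n"]) + P + 0.5 * P * (Z @ Z.T)
        assert cov.logdet == pytest.approx(np.linalg.slogdet(Vd)[1], rel=1e-10)

    def test_rank_update_layer(self, small_instance):
        si = small_instance
        g, y = si["g"], si["y"]
        cov = LowRankCovariance(0.7, si["factors"].phi, si["donor"], 0.5)
        B = si["factors"].phi * g[:, None]
        quad, ld = rank_update_quad_logdet(cov, B, 0.3, y)
        P = si["factors"].phi @ si["factors"].phi.T
        Z = si["donor"].Z
        G = np.diag(g)
        Vg = 0.7 * np.eye(si["n"]) + P + 0.5 * P * (Z @ Z.T) + 0.3 * G @ P @ G
        assert quad == pytest.approx(y @ np.linalg.solve(Vg, y), rel=1e-10)
        assert ld == pytest.approx(np.linalg.slogdet(Vg)[1], rel=1e-10)


def test_donor_design_one_hot_structure():
    d = DonorDesign.from_assignment(["a", "b", "a", "c", "b", "a"])
    assert d.Z.shape == (6, 3)
    assert np.all(d.Z.sum(axis=1) == 1)
    assert np.allclose(d.Z.T @ d.Z, np.diag([3, 2, 1]))


def test_variance_component_validation():
    with pytest.raises(ValueError):
        VarianceComponents(sigma2=0.0)
    with pytest.raises(ValueError):
        VarianceComponents(sigma2=1.0, delta_d=-0.1)
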