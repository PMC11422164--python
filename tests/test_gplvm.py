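import numpy as np
import pytest
from scipy.stats import norm, spearmanr

from dyngp.gplvm import (
    CovariateDesign,
    _pack,
    _value_grad,
    fit_gplvm,
    gplvm_bound,
)
from dyngp.kernels import KernelSpec
from dyngp.simulate import SimulationConfig, simulate_expression

SMOOTH = KernelSpec("ardse", variance=1.0, lengthscales=np.array([1.0]))


def test_bound_matches_dense_oracle(rng):
    """Matrix-normal bound equals the sum of J univariate GP likelihoods with
    explicit dense N x N column covariance."""
    n, J, m, q = 10, 3, 3, 1
    Y = rng.normal(size=(n, J))
    X = rng.normal(size=(n, q))
    T = rng.normal(size=(m, q))
    spec = KernelSpec("ardse", variance=1.0, lengthscales=np.array([0.9]))
    s2 = np.array([0.5, 1.1, 0.8])
    from dyngp.sparse_gp import build_factors

    f = build_factors(spec, X, T)
    V = np.eye(n) + f.phi @ f.phi.T
    dense = sum(
        norm.logpdf(Y[:, j], scale=1.0).sum() * 0.0  # placeholder, replaced below
        for j in range(0)
    )
    from scipy.stats import multivariate_normal

    dense = sum(multivariate_normal.logpdf(Y[:, j], np.zeros(n), s2[j] * V)
                for j in range(J))
    dense -= 0.5 * J * f.ktilde_diag.sum()
    assert gplvm_bound(Y, X, T, spec, s2) == pytest.approx(dense, rel=1e-8)


def test_bound_with_single_gene_reduces_to_h0(rng):
    from dyngp.sparse_gp import VarianceComponents, build_factors, titsias_bound

    n, m = 12, 4
    Y = rng.normal(size=(n, 1))
    X = rng.normal(size=(n, 1))
    T = rng.normal(size=(m, 1))
    s1 = 0.7
    spec = KernelSpec("ardse", variance=1.0, lengthscales=np.array([0.9]))
    b = gplvm_bound(Y, X, T, spec, np.array([s1]))
    f = build_factors(spec.with_params(variance=s1), X, T)
    b_h0 = titsias_bound(Y[:, 0], f, VarianceComponents(sigma2=s1), hypothesis="H0")
    assert b == pytest.approx(b_h0, rel=1e-10)


def test_zero_covariate_variance_matches_plain_bound(rng):
    n, J, m = 10, 4, 3
    Y = rng.normal(size=(n, J))
    X = rng.normal(size=(n, 1))
    T = rng.normal(size=(m, 1))
    spec = KernelSpec("ardse", variance=1.0, lengthscales=np.array([1.0]))
    s2 = np.full(J, 0.9)
    W0 = np.zeros((n, 2))
    assert gplvm_bound(Y, X, T, spec, s2, W=W0) == pytest.approx(
        gplvm_bound(Y, X, T, spec, s2), rel=1e-12)


def test_analytic_gradient_matches_finite_differences(rng):
    n, m, q, J = 9, 3, 2, 4
    Y = rng.normal(size=(n, J))
    X = rng.normal(size=(n, q))
    T = rng.normal(size=(m, q))
    design = CovariateDesign.from_labels(donor=rng.integers(0, 3, size=n))
    tmpl = KernelSpec("ardse", variance=1.0, lengthscales=np.ones(q),
                      periodic_dims=(0,))
    p0 = _pack(X, T, np.log([0.8, 1.3]), np.log(0.5 * np.var(Y, axis=0)),
               np.log([0.15]))
    _, g0 = _value_grad(p0, Y, tmpl, design, n, m, q, J, 1)
    eps = 1e-6
    for i in range(len(p0)):
        pp, pm = p0.copy(), p0.copy()
        pp[i] += eps
        pm[i] -= eps
        fp, _ = _value_grad(pp, Y, tmpl, design, n, m, q, J, 1)
        fm, _ = _value_grad(pm, Y, tmpl, design, n, m, q, J, 1)
        assert g0[i] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4, abs=1e-6)


def test_latent_recovery_on_smooth_trajectory():
    cfg = SimulationConfig(n_donors=12, cells_per_donor=10, sigma2=0.3,
                           kernel=SMOOTH, seed=42)
    Y, truth = simulate_expression(cfg, J=25)
    fit = fit_gplvm(Y - Y.mean(axis=0), q=1, m=12, seed=0)
    rho = abs(spearmanr(fit.latent[:, 0], truth["X"][:, 0]).statistic)
    assert rho >= 0.9
    assert fit.latent[:, 0].std() == pytest.approx(1.0, abs=1e-6)


def test_periodic_dimension_recovers_planted_phase():
    rng = np.random.default_rng(5)
    n, J = 150, 30
    phase = rng.uniform(0, 2 * np.pi, n)
    A = rng.normal(size=(2, J))
    Y = (np.cos(phase)[:, None] * A[0] + np.sin(phase)[:, None] * A[1]
         + 0.3 * rng.normal(size=(n, J)))
    fit = fit_gplvm(Y - Y.mean(axis=0), q=1, m=12, periodic_first_dim=True, seed=0)
    est = fit.latent[:, 0]
    assert np.all((est >= 0) & (est < 2 * np.pi))

    def circ_corr(a, b):
        sa = np.sin(a - np.angle(np.mean(np.exp(1j * a))))
        sb = np.sin(b - np.angle(np.mean(np.exp(1j * b))))
        return np.sum(sa * sb) / np.sqrt(np.sum(sa**2) * np.sum(sb**2))

    assert abs(circ_corr(est, phase)) >= 0.8


def test_covariate_design_reduces_batch_leakage():
    """Fitting with the batch design at least halves latent-batch R^2."""
    cfg = SimulationConfig(n_donors=12, cells_per_donor=10, sigma2=0.3,
                           kernel=SMOOTH, seed=9)
    rng = np.random.default_rng(9)
    X_true = rng.standard_normal((cfg.n, 1))
    batch = np.tile([0, 1], cfg.n // 2)
    Y, truth = simulate_expression(cfg, J=25, X=X_true, batch=batch, batch_sd=1.5,
                                   rng=rng)
    Yc = Y - Y.mean(axis=0)
    design = CovariateDesign.from_labels(batch=batch)

    def batch_r2(lat):
        mu = np.array([lat[batch == b].mean() for b in (0, 1)])[batch]
        return 1.0 - np.var(lat - mu) / np.var(lat)

    fit_adj = fit_gplvm(Yc, q=1, m=12, covariates=design, seed=0)
    fit_raw = fit_gplvm(Yc, q=1, m=12, seed=0)
    assert batch_r2(fit_adj.latent[:, 0]) <= 0.5 * batch_r2(fit_raw.latent[:, 0])


def test_linear_noiseless_limit_matches_pca():
    rng = np.random.default_rng(11)
    n, J = 80, 12
    x = rng.standard_normal(n)
    load = rng.normal(size=J)
    Y = np.outer(x, load)
    fit = fit_gplvm(Y - Y.mean(axis=0), q=1, m=15, seed=0)
    from sklearn.decomposition import PCA

    pc1 = PCA(1).fit_transform(Y - Y.mean(axis=0))[:, 0]
    assert abs(np.corrcoef(fit.latent[:, 0], pc1)[0, 1]) >= 0.95


def test_invalid_dimensions_rejected(rng):
    Y = rng.normal(size=(10, 4))
    with pytest.raises(ValueError):
        fit_gplvm(Y, q=0)
    with pytest.raises(ValueError):
        fit_gplvm(Y, q=5)
    with pytest.raises(ValueError):
        fit_gplvm(Y, q=1, m=11)
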