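"""GP latent variable model for inferring cellular state (pseudotime).

The expression matrix Y (N cells x J genes) is modelled gene-wise by the
baseline sparse GP, sharing the latent inputs X across genes.  Integrating
the inducing values (and optional covariate random effects b_j with
b_j ~ N(0, sigma_j^2 Delta)) gives the matrix-normal Titsias bound

    log p(Y | X) >= log MN(Y | 0, Sigma, I + K_NM K_MM^{-1} K_MN + W Delta W^T)
                    - (J/2) tr{Ktilde_NN},

with Sigma = diag(sigma_j^2) the per-gene residual variances and the kernel
variance pinned at 1 for identifiability.  Latent coordinates carry an iid
standard-normal prior; a designated periodic first dimension (cell-cycle
phase) uses the periodic x ARD-SE product kernel and no Gaussian prior.

The bound is maximized by L-BFGS with analytic gradients; no N x N matrix is
ever formed (cost O(N (M+P)^2 + N J (M+P)) per evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .kernels import (
    KernelSpec,
    grad_wrt_log_lengthscale,
    grad_wrt_second_input,
)
from .sparse_gp import LOG2PI, LowRankCovariance, build_factors


@dataclass
class CovariateDesign:
    """One-hot covariate design W with a scalar variance ratio per block.

    `blocks` maps block names (e.g. "donor", "batch") to column index arrays;
    Delta is diagonal with one shared value per block.
    """

    matrix: np.ndarray
    blocks: dict
    variance_ratios: dict = field(default_factory=dict)

    @classmethod
    def from_labels(cls, **label_arrays) -> "CovariateDesign":
        cols, blocks, start = [], {}, 0
        for name, labels in label_arrays.items():
            labels = np.asarray(labels)
            levels = np.unique(labels)
            block = np.zeros((labels.shape[0], levels.shape[0]))
            for i, lev in enumerate(levels):
                block[labels == lev, i] = 1.0
            cols.append(block)
            blocks[name] = np.arange(start, start + levels.shape[0])
            start += levels.shape[0]
        return cls(np.concatenate(cols, axis=1), blocks)

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


@dataclass
class LatentFit:
    """GPLVM output: latent states and the fitted model around them."""

    latent: np.ndarray            # N x Q, standardized (periodic dim mod 2pi)
    latent_raw: np.ndarray        # N x Q as optimized
    residual_variances: np.ndarray  # sigma_j^2, length J
    inducing: np.ndarray          # M x Q
    kernel: KernelSpec            # variance pinned at 1
    delta: dict                   # covariate block -> fitted variance ratio
    bound: float
    converged: bool
    n_iter: int = 0


def _scaled_W(design: CovariateDesign | None, log_delta: np.ndarray):
    if design is None:
        return None
    scale = np.zeros(design.p)
    for b, (name, idx) in enumerate(design.blocks.items()):
        scale[idx] = np.exp(0.5 * log_delta[b])
    return design.matrix * scale[None, :]


def gplvm_bound(Y: np.ndarray, X: np.ndarray, T: np.ndarray, spec: KernelSpec,
                sigma2s: np.ndarray, W: np.ndarray | None = None) -> float:
    """Evaluate the matrix-normal Titsias bound (kernel variance must be 1).

    `W` is the covariate design with the sqrt variance ratios already folded
    into its columns (i.e. the covariance term is W W^T).
    """
    Y = np.asarray(Y, dtype=float)
    n, J = Y.shape
    factors = build_factors(spec, X, T)
    U = factors.phi if W is None else np.concatenate([factors.phi, W], axis=1)
    cov = LowRankCovariance(1.0, U)
    Yt = Y / np.sqrt(np.asarray(sigma2s, dtype=float))[None, :]
    quad = float(np.sum(Yt * cov.solve(Yt)))
    return (-0.5 * n * J * LOG2PI - 0.5 * n * float(np.sum(np.log(sigma2s)))
            - 0.5 * J * cov.logdet - 0.5 * quad
            - 0.5 * J * factors.trace_ktilde)


def _pack(X, T, log_rho, log_sigma2s, log_delta):
    return np.concatenate([X.ravel(), T.ravel(), log_rho, log_sigma2s, log_delta])


def _unpack(p, n, m, q, J, nb):
    X = p[: n * q].reshape(n, q)
    T = p[n * q : (n + m) * q].reshape(m, q)
    k = (n + m) * q
    return X, T, p[k : k + q], p[k + q : k + q + J], p[k + q + J : k + q + J + nb]


def _value_grad(params, Y, template: KernelSpec, design: CovariateDesign | None,
                n, m, q, J, nb):
    """Negative (bound + latent prior) and gradient; the analytic core."""
    X, T, log_rho, log_s2, log_delta = _unpack(params, n, m, q, J, nb)
    spec = template.with_params(lengthscales=np.exp(log_rho))
    try:
        factors = build_factors(spec, X, T)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(params)
    phi, C, knm = factors.phi, factors.C, factors.knm
    kmm = factors.chol_kmm @ factors.chol_kmm.T
    Wsc = _scaled_W(design, log_delta)
    U = phi if Wsc is None else np.concatenate([phi, Wsc], axis=1)
    cov = LowRankCovariance(1.0, U)
    s2 = np.exp(log_s2)
    Yt = Y / np.sqrt(s2)[None, :]
    Q = cov.solve(Yt)                       # V^{-1} Ytilde, N x J
    quad_j = np.sum(Yt * Q, axis=0)
    bound = (-0.5 * n * J * LOG2PI - 0.5 * n * float(np.sum(log_s2))
             - 0.5 * J * cov.logdet - 0.5 * float(np.sum(quad_j))
             - 0.5 * J * factors.trace_ktilde)
    nonper = [d for d in range(q) if d not in spec.periodic_dims]
    prior = -0.5 * float(np.sum(X[:, nonper] ** 2)) if nonper else 0.0
    total = bound + prior
    if not np.isfinite(total):
        return 1e10, np.zeros_like(params)

    VinvC = cov.solve(C)
    QtC = Q.T @ C                            # J x M
    # dL/dK_NM and dL/dK_MM (V term + trace penalty)
    G_knm = -J * VinvC + Q @ QtC + J * C
    G_kmm = (0.5 * J * (C.T @ VinvC) - 0.5 * (QtC.T @ QtC)
             - 0.5 * J * (C.T @ C))

    gX = np.zeros_like(X)
    gT = np.zeros_like(T)
    g_rho = np.zeros(q)
    for d in range(q):
        e_nm = grad_wrt_second_input(spec, knm, X, T, d)
        e_mm = grad_wrt_second_input(spec, kmm, T, T, d)
        gX[:, d] = -np.sum(G_knm * e_nm, axis=1)
        gT[:, d] = (np.sum(G_knm * e_nm, axis=0)
                    + np.sum((G_kmm + G_kmm.T) * e_mm, axis=0))
        g_rho[d] = (np.sum(G_knm * grad_wrt_log_lengthscale(spec, knm, X, T, d))
                    + np.sum(G_kmm * grad_wrt_log_lengthscale(spec, kmm, T, T, d)))
    for d in nonper:
        gX[:, d] -= X[:, d]

    g_s2 = -0.5 * n + 0.5 * quad_j
    g_delta = np.zeros(nb)
    if design is not None:
        VinvW = cov.solve(Wsc)
        QtW = Q.T @ Wsc                      # J x P
        per_col = -0.5 * J * np.sum(Wsc * VinvW, axis=0) + 0.5 * np.sum(QtW**2, axis=0)
        for b, (name, idx) in enumerate(design.blocks.items()):
            g_delta[b] = np.sum(per_col[idx])   # d/d log delta_b (W already carries sqrt delta)
    grad = _pack(gX, gT, g_rho, g_s2, g_delta)
    return -total, -grad


def _init_latent(Y: np.ndarray, q: int, periodic_first: bool, rng) -> np.ndarray:
    from sklearn.decomposition import PCA

    n_pc = q + 1 if periodic_first else q
    n_pc = min(n_pc, min(Y.shape) - 1) or 1
    pcs = PCA(n_components=n_pc, random_state=0).fit_transform(Y - Y.mean(axis=0))
    pcs = pcs / np.maximum(pcs.std(axis=0), 1e-8)
    if not periodic_first:
        return pcs[:, :q].copy()
    X0 = np.zeros((Y.shape[0], q))
    if pcs.shape[1] >= 2:
        X0[:, 0] = np.mod(np.arctan2(pcs[:, 1], pcs[:, 0]), 2 * np.pi)
    else:
        X0[:, 0] = rng.uniform(0, 2 * np.pi, size=Y.shape[0])
    for d in range(1, q):
        col = min(d + 1, pcs.shape[1] - 1)
        X0[:, d] = pcs[:, col]
    return X0


def _candidate_inits(Y, q, periodic_first, rng):
    """Initial latent configurations: principal components plus (for the
    non-periodic case) Isomap embeddings at two neighborhood sizes.  The
    geodesic inits resolve global orderings that linear PCA folds over; the
    achieved bound arbitrates."""
    inits = [_init_latent(Y, q, periodic_first, rng)]
    if periodic_first:
        return inits
    from sklearn.manifold import Isomap

    n = Y.shape[0]
    for nn in (10, 25):
        if nn >= n:
            continue
        try:
            iso = Isomap(n_components=q, n_neighbors=nn).fit_transform(Y)
        except Exception:
            continue
        sd = np.maximum(iso.std(axis=0), 1e-8)
        inits.append((iso - iso.mean(axis=0)) / sd)
    return inits


def _fit_from(Y, X0, q, m, template, covariates, seed, maxiter, stages):
    """Lengthscale-continuation fit from one initial X: optimize with rho
    frozen at each stage value (largest first), then release everything."""
    from sklearn.cluster import KMeans

    n, J = Y.shape
    nb = len(covariates.blocks) if covariates is not None else 0
    if m < n:
        T0 = KMeans(n_clusters=m, n_init=4, random_state=seed % (2**31)).fit(X0).cluster_centers_
    else:
        T0 = X0.copy()
    s2_0 = np.maximum(0.5 * np.var(Y, axis=0), 1e-4)
    p = _pack(X0, T0, np.log(np.full(q, stages[0])), np.log(s2_0),
              np.full(nb, np.log(0.1)))
    n_xt = (n + m) * q
    args = (Y, template, covariates, n, m, q, J, nb)

    def frozen_rho(pp):
        f, g = _value_grad(pp, *args)
        g = g.copy()
        g[n_xt : n_xt + q] = 0.0
        return f, g

    for rho_fix in stages:
        p[n_xt : n_xt + q] = np.log(rho_fix)
        p = optimize.minimize(frozen_rho, p, jac=True, method="L-BFGS-B",
                              options={"maxiter": 150}).x
    return optimize.minimize(_value_grad, p, args=args, jac=True,
                             method="L-BFGS-B", options={"maxiter": maxiter})


def fit_gplvm(Y: np.ndarray, q: int = 1, m: int = 10,
              covariates: CovariateDesign | None = None,
              periodic_first_dim: bool = False, seed: int = 0,
              maxiter: int = 800, stages=(4.0, 1.0)) -> LatentFit:
    """Maximize the GPLVM bound plus the standard-normal latent prior.

    The bound is multimodal in X, so the fit runs a lengthscale continuation
    (rho frozen at each of `stages` while X, T, Sigma organize, largest
    first, then everything free) from several initial configurations (PCA
    and Isomap; the periodic phase, if any, from the angle of the first two
    PCs) and keeps the solution with the best final bound.
    """
    Y = np.asarray(Y, dtype=float)
    n, J = Y.shape
    if q < 1 or q > min(n, J):
        raise ValueError("latent dimension must satisfy 1 <= Q <= min(N, J)")
    if m > n:
        raise ValueError("more inducing points than samples")
    rng = np.random.default_rng(seed)
    periodic = (0,) if periodic_first_dim else ()
    template = KernelSpec("ardse", variance=1.0, lengthscales=np.ones(q),
                          periodic_dims=periodic)
    nb = len(covariates.blocks) if covariates is not None else 0
    best = None
    for r, X0 in enumerate(_candidate_inits(Y, q, periodic_first_dim, rng)):
        res = _fit_from(Y, X0, q, m, template, covariates, seed + r, maxiter,
                        stages)
        if best is None or res.fun < best.fun:
            best = res
    res = best
    X, T, log_rho, log_s2, log_delta = _unpack(res.x, n, m, q, J, nb)
    spec = template.with_params(lengthscales=np.exp(log_rho))
    latent = X.copy()
    for d in range(q):
        if d in spec.periodic_dims:
            latent[:, d] = np.mod(latent[:, d], 2 * np.pi)
        else:
            sd = latent[:, d].std()
            latent[:, d] = (latent[:, d] - latent[:, d].mean()) / (sd if sd > 0 else 1.0)
    delta = {}
    if covariates is not None:
        for b, name in enumerate(covariates.blocks):
            delta[name] = float(np.exp(log_delta[b]))
    return LatentFit(
        latent=latent, latent_raw=X, residual_variances=np.exp(log_s2),
        inducing=T, kernel=spec, delta=delta, bound=float(-res.fun),
        converged=bool(res.success), n_iter=int(res.nit),
    )
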