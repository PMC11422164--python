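"""Inducing-point machinery: Nyström factors, Titsias bounds, low-rank solves.

A sparse GP summarizes the full N x N kernel matrix through M inducing points
T, with

    f_bar = K_NM K_MM^{-1} u,      Ktilde_NN = K_NN - K_NM K_MM^{-1} K_MN.

All downstream covariances are "noise + low rank":

    V    = s2 I + K_NM K_MM^{-1} K_MN
    V_d  = V + delta_d (K_NM K_MM^{-1} K_MN) . (Z Z^T)      (. = Hadamard)
    V_g  = V_d + delta_g G K_NM K_MM^{-1} K_MN G,  G = diag(g)

and are never materialized densely: writing Phi = K_NM L^{-T} with
L = chol(K_MM), the Hadamard term equals sum_d (D_d Phi)(D_d Phi)^T over
donors d (D_d masks the rows of donor d), so V_d = D + U U^T with
block-structured U.  The inner (Woodbury) matrix is an *arrowhead* of
N_d + 1 blocks of size M for unrelated (one-hot) donors and is eliminated
donor-by-donor in O(N_d M^3); a general low-rank kinship Z falls back to a
dense inner factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .kernels import KernelSpec, add_jitter, eval_kernel, kernel_diag

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class InducingPoints:
    """Coordinates T of the M pseudo-inputs, one row per inducing point."""

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))

    @property
    def m(self) -> int:
        return self.coords.shape[0]


@dataclass
class VarianceComponents:
    """Residual variance and the donor / genetic variance ratios."""

    sigma2: float = 1.0
    delta_d: float = 0.0
    delta_g: float = 0.0

    def __post_init__(self):
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        if self.delta_d < 0 or self.delta_g < 0:
            raise ValueError("variance ratios must be nonnegative")


class DonorDesign:
    """Donor (kinship) structure R = Z Z^T.

    For repeated samples from unrelated donors, Z is the one-hot donor
    indicator matrix; a general kinship matrix is accommodated through a
    truncated eigendecomposition R ~= Z Z^T.
    """

    def __init__(self, Z: np.ndarray, one_hot: bool, assignment=None):
        self.Z = np.asarray(Z, dtype=float)
        self.one_hot = bool(one_hot)
        self.assignment = assignment
        if one_hot:
            self.groups = [np.flatnonzero(self.Z[:, j] > 0) for j in range(self.Z.shape[1])]
        else:
            self.groups = None

    @classmethod
    def from_assignment(cls, assignment) -> "DonorDesign":
        assignment = np.asarray(assignment)
        donors, idx = np.unique(assignment, return_inverse=True)
        Z = np.zeros((assignment.shape[0], donors.shape[0]))
        Z[np.arange(assignment.shape[0]), idx] = 1.0
        return cls(Z, one_hot=True, assignment=idx)

    @classmethod
    def from_kinship(cls, R: np.ndarray, mass: float = 0.999) -> "DonorDesign":
        """Factor a PSD kinship matrix as Z Z^T, keeping eigenvalue mass >= `mass`."""
        w, V = np.linalg.eigh(np.asarray(R, dtype=float))
        w = np.clip(w, 0.0, None)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        cum = np.cumsum(w) / np.sum(w)
        rank = int(np.searchsorted(cum, mass) + 1)
        Z = V[:, :rank] * np.sqrt(w[:rank])
        return cls(Z, one_hot=False)

    @property
    def n_donors(self) -> int:
        return self.Z.shape[1]


@dataclass
class SparseGPFactors:
    """Precomputed Nyström quantities for fixed (X, T, kernel)."""

    spec: KernelSpec
    X: np.ndarray
    T: np.ndarray
    knm: np.ndarray          # K_NM
    chol_kmm: np.ndarray     # lower Cholesky factor of K_MM (jittered)
    C: np.ndarray            # K_NM K_MM^{-1}
    phi: np.ndarray          # K_NM L^{-T}; Phi Phi^T = K_NM K_MM^{-1} K_MN
    kdiag: np.ndarray        # diag of K_NN
    ktilde_diag: np.ndarray  # diag of Ktilde_NN, clipped at 0

    @property
    def n(self) -> int:
        return self.knm.shape[0]

    @property
    def m(self) -> int:
        return self.knm.shape[1]

    @property
    def trace_ktilde(self) -> float:
        return float(np.sum(self.ktilde_diag))


def build_factors(spec: KernelSpec, X: np.ndarray, T) -> SparseGPFactors:
    """Evaluate and factor the kernel blocks K_NM, K_MM for inducing points T."""
    if isinstance(T, InducingPoints):
        T = T.coords
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape[0] > X.shape[0]:
        raise ValueError("more inducing points than data points")
    kmm_raw = eval_kernel(spec, T, T)
    for rel in (1e-8, 1e-6, 1e-4):  # escalate if the factorization fails
        kmm = add_jitter(kmm_raw, rel=rel)
        try:
            L = cholesky(kmm, lower=True)
            break
        except np.linalg.LinAlgError:
            if rel == 1e-4:
                raise
    knm = eval_kernel(spec, X, T)
    phi = solve_triangular(L, knm.T, lower=True).T            # K_NM L^{-T}
    C = solve_triangular(L.T, phi.T, lower=False).T           # K_NM K_MM^{-1}
    kdiag = kernel_diag(spec, X)
    ktilde = np.clip(kdiag - np.sum(phi * phi, axis=1), 0.0, None)
    return SparseGPFactors(spec, X, T, knm, L, C, phi, kdiag, ktilde)


class LowRankCovariance:
    """Matrix-free handle on V_d = D + U U^T (D diagonal noise).

    Parameters
    ----------
    noise:
        Scalar or N-vector of noise variances (the diagonal D).
    phi:
        N x M global low-rank block (kernel part of V).
    donor, delta_d:
        Optional donor design and ratio for the Hadamard term; `phi_donor`
        lets the donor GP use a different kernel factor than the baseline
        (used by the static+dynamic decomposition).
    """

    def __init__(self, noise, phi, donor: DonorDesign | None = None,
                 delta_d: float = 0.0, phi_donor: np.ndarray | None = None):
        phi = np.asarray(phi, dtype=float)
        n = phi.shape[0]
        self.n = n
        d = np.asarray(noise, dtype=float)
        self.d = np.full(n, float(d)) if d.ndim == 0 else d
        if np.any(self.d <= 0):
            raise ValueError("noise variances must be positive")
        self.phi = phi
        self.donor = donor if (donor is not None and delta_d > 0) else None
        self.delta_d = float(delta_d)
        self.phi_donor = phi if phi_donor is None else np.asarray(phi_donor, dtype=float)
        self._factor()

    def _factor(self):
        d, phi = self.d, self.phi
        m = phi.shape[1]
        t = phi / d[:, None]
        S00 = np.eye(m) + phi.T @ t
        if self.donor is None:
            self._mode = "plain"
            self._c00 = cho_factor(S00, lower=True)
            self._logdet = float(np.sum(np.log(d))
                                 + 2.0 * np.sum(np.log(np.diag(self._c00[0]))))
            return
        sd = np.sqrt(self.delta_d)
        pd = self.phi_donor
        if self.donor.one_hot:
            self._mode = "arrowhead"
            m2 = pd.shape[1]
            self._cross, self._cdd = [], []
            S00s = S00.copy()
            logdet = float(np.sum(np.log(d)))
            for idx in self.donor.groups:
                pi = pd[idx]
                ti = pi / d[idx, None]
                Sdd = np.eye(m2) + self.delta_d * (pi.T @ ti)
                S0d = sd * (phi[idx].T @ ti)
                cdd = cho_factor(Sdd, lower=True)
                S00s -= S0d @ cho_solve(cdd, S0d.T)
                logdet += 2.0 * np.sum(np.log(np.diag(cdd[0])))
                self._cross.append(S0d)
                self._cdd.append(cdd)
            self._c00 = cho_factor(S00s, lower=True)
            self._logdet = logdet + 2.0 * np.sum(np.log(np.diag(self._c00[0])))
        else:
            self._mode = "dense"
            Z = self.donor.Z
            blocks = [phi] + [sd * Z[:, [j]] * pd for j in range(Z.shape[1])]
            U = np.concatenate(blocks, axis=1)
            self._U = U
            S = np.eye(U.shape[1]) + U.T @ (U / d[:, None])
            self._cS = cho_factor(S, lower=True)
            self._logdet = float(np.sum(np.log(d))
                                 + 2.0 * np.sum(np.log(np.diag(self._cS[0]))))

    @property
    def logdet(self) -> float:
        return self._logdet

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Return V_d^{-1} rhs for a vector or matrix right-hand side."""
        rhs = np.asarray(rhs, dtype=float)
        vec = rhs.ndim == 1
        R = rhs[:, None] if vec else rhs
        t = R / self.d[:, None]
        if self._mode == "dense":
            a = self._U.T @ t
            x = cho_solve(self._cS, a)
            out = t - (self._U @ x) / self.d[:, None]
            return out[:, 0] if vec else out
        a0 = self.phi.T @ t
        if self._mode == "plain":
            x0 = cho_solve(self._c00, a0)
            out = t - (self.phi @ x0) / self.d[:, None]
            return out[:, 0] if vec else out
        sd = np.sqrt(self.delta_d)
        pd = self.phi_donor
        ads = []
        rhs0 = a0.copy()
        for idx, S0d, cdd in zip(self.donor.groups, self._cross, self._cdd):
            ad = sd * (pd[idx].T @ t[idx])
            ads.append(ad)
            rhs0 -= S0d @ cho_solve(cdd, ad)
        x0 = cho_solve(self._c00, rhs0)
        corr = self.phi @ x0
        for idx, S0d, cdd, ad in zip(self.donor.groups, self._cross, self._cdd, ads):
            xd = cho_solve(cdd, ad - S0d.T @ x0)
            corr[idx] += sd * (pd[idx] @ xd)
        out = t - corr / self.d[:, None]
        return out[:, 0] if vec else out

    def quad(self, y: np.ndarray) -> float:
        return float(y @ self.solve(y))

    def trace_inv(self) -> float:
        """tr(V_d^{-1}); used by gradient code (cheap for the plain mode only)."""
        if self._mode != "plain":
            raise NotImplementedError("trace_inv implemented for the no-donor mode")
        t = self.phi / self.d[:, None]
        B = cho_solve(self._c00, t.T)
        return float(np.sum(1.0 / self.d) - np.sum(t.T * B))

    def gaussian_loglik(self, y: np.ndarray) -> float:
        """log N(y | 0, V_d) without the Titsias trace penalty."""
        return -0.5 * (self.n * LOG2PI + self.logdet + self.quad(y))


def rank_update_quad_logdet(base: LowRankCovariance, B: np.ndarray, scale: float,
                            y: np.ndarray):
    """Quadratic form and log-determinant of  V = base + scale * B B^T.

    Layered Woodbury: returns (y^T V^{-1} y, logdet V). Used for the H2
    covariance V_g = V_d + delta_g (G Phi)(G Phi)^T.
    """
    if scale == 0.0:
        return base.quad(y), base.logdet
    VinvB = base.solve(B)
    Sg = np.eye(B.shape[1]) + scale * (B.T @ VinvB)
    cg = cho_factor(Sg, lower=True)
    b = B.T @ base.solve(y)
    quad = base.quad(y) - scale * float(b @ cho_solve(cg, b))
    logdet = base.logdet + 2.0 * float(np.sum(np.log(np.diag(cg[0]))))
    return quad, logdet


def lowrank_solve(factors: SparseGPFactors, donor: DonorDesign | None,
                  vc: VarianceComponents, rhs: np.ndarray) -> np.ndarray:
    """V_d^{-1} rhs via the Woodbury identity on sigma^2 I + A B^{-1} A^T."""
    cov = LowRankCovariance(vc.sigma2, factors.phi, donor, vc.delta_d)
    return cov.solve(rhs)


def titsias_bound(y: np.ndarray, factors: SparseGPFactors, vc: VarianceComponents,
                  donor: DonorDesign | None = None, g: np.ndarray | None = None,
                  hypothesis: str = "H0") -> float:
    """Titsias lower bound L2^h for h in {H0, H1, H2}.

    H0: V = s2 I + Phi Phi^T, penalty tr{Ktilde}/(2 s2).
    H1: adds the donor Hadamard term, penalty (1+delta_d) tr{Ktilde}/(2 s2).
    H2: adds delta_g (G Phi)(G Phi)^T, penalty gains delta_g tr{G Ktilde G}/(2 s2).
    """
    y = np.asarray(y, dtype=float)
    s2 = vc.sigma2
    if hypothesis == "H0":
        cov = LowRankCovariance(s2, factors.phi)
        penalty = factors.trace_ktilde / (2.0 * s2)
        return cov.gaussian_loglik(y) - penalty
    if donor is None:
        raise ValueError("H1/H2 require a donor design")
    cov = LowRankCovariance(s2, factors.phi, donor, vc.delta_d)
    penalty = (1.0 + vc.delta_d) * factors.trace_ktilde / (2.0 * s2)
    if hypothesis == "H1":
        return cov.gaussian_loglik(y) - penalty
    if hypothesis != "H2":
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if g is None:
        raise ValueError("H2 requires a genotype vector")
    g = np.asarray(g, dtype=float)
    B = factors.phi * g[:, None]
    quad, logdet = rank_update_quad_logdet(cov, B, vc.delta_g, y)
    penalty += vc.delta_g * float(np.sum(g * g * factors.ktilde_diag)) / (2.0 * s2)
    return -0.5 * (factors.n * LOG2PI + logdet + quad) - penalty
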