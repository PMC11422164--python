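"""Kernel functions for GP-based association mapping.

The workhorse is the automatic relevance determination squared exponential
(ARD-SE) kernel

    k(x_j, x_k) = sigma^2 * exp[ - sum_q (x_jq - x_kq)^2 / (2 rho_q) ],

where ``rho_q`` plays the role of a squared characteristic length scale per
input dimension (the relevance of dimension q is 1/rho_q).  Designated
*periodic* dimensions replace their squared-distance term by
``sin^2((x_j - x_k)/2) / rho``, which makes the kernel 2*pi-periodic in that
coordinate — used to model latent cell-cycle phase.  The *static+dynamic*
composite

    K* = sigma^2 * exp(-rho0) * 1 1^T + K

adds a constant (state-independent) covariance component whose log-weight
``rho0`` controls the ratio of static to dynamic variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FAMILIES = ("linear", "ardse", "periodic_ardse", "static_dynamic")


@dataclass
class KernelSpec:
    """Kernel family plus hyperparameters.

    Parameters
    ----------
    family:
        One of ``linear``, ``ardse``, ``periodic_ardse`` (ARD-SE with the
        first input dimension periodic), ``static_dynamic`` (ARD-SE plus a
        constant term ``variance * exp(-static_log_weight)``).
    variance:
        Kernel variance sigma^2 (> 0).
    lengthscales:
        Vector of Q positive values rho_1..rho_Q (squared-lengthscale
        parameterization: the SE exponent denominator is ``2 * rho_q``).
    static_log_weight:
        rho0, only used by ``static_dynamic``.
    periodic_dims:
        Indices of input dimensions treated as 2*pi-periodic phases.
    """

    family: str = "ardse"
    variance: float = 1.0
    lengthscales: np.ndarray = field(default_factory=lambda: np.ones(1))
    static_log_weight: float = 0.0
    periodic_dims: tuple = ()

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if not self.variance > 0:
            raise ValueError("kernel variance must be positive")
        if np.any(self.lengthscales <= 0):
            raise ValueError("lengthscales must be positive")
        if self.family == "periodic_ardse":
            self.periodic_dims = (0,)

    @property
    def q(self) -> int:
        return self.lengthscales.shape[0]

    def with_params(self, **kw) -> "KernelSpec":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "variance": float(self.variance),
            "lengthscales": [float(r) for r in self.lengthscales],
            "static_log_weight": float(self.static_log_weight),
            "periodic_dims": list(self.periodic_dims),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(
            family=d["family"],
            variance=d.get("variance", 1.0),
            lengthscales=np.asarray(d.get("lengthscales", [1.0]), dtype=float),
            static_log_weight=d.get("static_log_weight", 0.0),
            periodic_dims=tuple(d.get("periodic_dims", ())),
        )


def _check_inputs(spec: KernelSpec, X1: np.ndarray, X2: np.ndarray):
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("input matrices have different numbers of columns")
    if spec.family != "linear" and X1.shape[1] != spec.q:
        raise ValueError(
            f"kernel has {spec.q} lengthscales but inputs have {X1.shape[1]} columns"
        )
    return X1, X2


def _se_exponent(spec: KernelSpec, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Negative exponent  sum_q d_q(x_j, x_k) / rho_q  of the (periodic) ARD-SE."""
    n1, n2 = X1.shape[0], X2.shape[0]
    expo = np.zeros((n1, n2))
    for q in range(spec.q):
        d = X1[:, q][:, None] - X2[:, q][None, :]
        if q in spec.periodic_dims:
            expo += np.sin(d / 2.0) ** 2 / spec.lengthscales[q]
        else:
            expo += d**2 / (2.0 * spec.lengthscales[q])
    return expo


def eval_kernel(spec: KernelSpec, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Evaluate k(X1, X2) for the given spec; rows(X1) x rows(X2) matrix."""
    X1, X2 = _check_inputs(spec, X1, X2)
    if spec.family == "linear":
        return spec.variance * X1 @ X2.T
    K = spec.variance * np.exp(-_se_exponent(spec, X1, X2))
    if spec.family == "static_dynamic":
        K = K + spec.variance * np.exp(-spec.static_log_weight)
    return K


def kernel_diag(spec: KernelSpec, X: np.ndarray) -> np.ndarray:
    """Diagonal of k(X, X) without forming the matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if spec.family == "linear":
        return spec.variance * np.sum(X * X, axis=1)
    d = np.full(X.shape[0], spec.variance)
    if spec.family == "static_dynamic":
        d = d + spec.variance * np.exp(-spec.static_log_weight)
    return d


def add_jitter(K: np.ndarray, rel: float = 1e-6) -> np.ndarray:
    """Relative jitter on the diagonal prior to Cholesky factorization."""
    K = np.asarray(K, dtype=float)
    scale = np.mean(np.diag(K))
    if scale <= 0:
        scale = 1.0
    return K + rel * scale * np.eye(K.shape[0])


# ---------------------------------------------------------------------------
# derivative helpers used by the fitting code (stationary families only)

def grad_wrt_log_lengthscale(
    spec: KernelSpec, K: np.ndarray, X1: np.ndarray, X2: np.ndarray, q: int
) -> np.ndarray:
    """dK/d(log rho_q) elementwise, given the evaluated K.

    For static_dynamic, the constant term does not depend on rho, so the
    derivative applies only to the SE part; the caller passes the full K and
    the constant offset is subtracted here.
    """
    X1, X2 = _check_inputs(spec, X1, X2)
    Kse = K
    if spec.family == "static_dynamic":
        Kse = K - spec.variance * np.exp(-spec.static_log_weight)
    d = X1[:, q][:, None] - X2[:, q][None, :]
    if q in spec.periodic_dims:
        return Kse * (np.sin(d / 2.0) ** 2 / spec.lengthscales[q])
    return Kse * (d**2 / (2.0 * spec.lengthscales[q]))


def grad_wrt_second_input(
    spec: KernelSpec, K: np.ndarray, X1: np.ndarray, X2: np.ndarray, q: int
) -> np.ndarray:
    """Elementwise dK[j,m]/dX2[m,q] (i.e. derivative in the second argument)."""
    X1, X2 = _check_inputs(spec, X1, X2)
    Kse = K
    if spec.family == "static_dynamic":
        Kse = K - spec.variance * np.exp(-spec.static_log_weight)
    d = X1[:, q][:, None] - X2[:, q][None, :]
    if q in spec.periodic_dims:
        return Kse * (np.sin(d) / (2.0 * spec.lengthscales[q]))
    return Kse * (d / spec.lengthscales[q])
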