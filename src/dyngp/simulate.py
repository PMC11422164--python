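"""Synthetic data with the exact generative structure the mapping model assumes.

Phenotypes are drawn from

    y = alpha + beta . g + gamma + eps,
    alpha ~ N(0, K),  beta ~ N(0, delta_g K),  gamma ~ N(0, delta_d K . R),

with K a dense kernel matrix over the (drawn or supplied) states X, R = Z Z^T
the donor indicator outer product, and eps ~ N(0, sigma2 I).  Optional static
terms alpha0 1 + beta0 g + gamma0 (gamma0 ~ N(0, sigma2 delta_d0 R)) extend the
model to the static+dynamic decomposition setting.  Draws are dense and exact
(no inducing points), so the generator is a model-faithful oracle for the
sparse inference path: any approximation error shows up as estimation error,
not as a shared artifact.

Poisson phenotypes use the same latent sum as the log-mean, plus a constant
offset controlling the count scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, add_jitter, eval_kernel
from .sparse_gp import DonorDesign


@dataclass
class SimulationConfig:
    """Study conditions for the generator; the defaults are the reference
    conditions used throughout validation (30 donors x 10 cells, ARD-SE kernel
    with unit variance and rho = 0.3 on standard-normal states, residual
    variance 0.5, donor ratio 0.3)."""

    n_donors: int = 30
    cells_per_donor: int = 10
    n_variants: int = 100
    maf_range: tuple = (0.1, 0.5)
    q: int = 1
    kernel: KernelSpec = field(
        default_factory=lambda: KernelSpec("ardse", variance=1.0, lengthscales=np.array([0.3]))
    )
    sigma2: float = 0.5
    delta_d: float = 0.3
    delta_g: float = 0.0
    alpha0: float = 0.0
    beta0: float = 0.0
    delta_d0: float = 0.0
    family: str = "gaussian"
    log_mean_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.delta_d < 0 or self.delta_g < 0 or self.delta_d0 < 0:
            raise ValueError("variance components must be nonnegative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf range must lie in (0, 0.5]")
        if self.family not in ("gaussian", "poisson"):
            raise ValueError("family must be gaussian or poisson")

    @property
    def n(self) -> int:
        return self.n_donors * self.cells_per_donor


def simulate_genotypes(config: SimulationConfig, rng=None):
    """Per-donor dosages Binomial(2, maf) expanded to cells via Z.

    Returns (dosages N x V, donor design, donor-level dosages N_d x V, mafs).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_variants)
    donor_dose = rng.binomial(2, mafs[None, :], size=(config.n_donors, config.n_variants))
    assignment = np.repeat(np.arange(config.n_donors), config.cells_per_donor)
    donor = DonorDesign.from_assignment(assignment)
    dosages = donor_dose[assignment].astype(float)
    return dosages, donor, donor_dose.astype(float), mafs


def simulate_states(config: SimulationConfig, rng=None) -> np.ndarray:
    """Latent states X, standard normal per dimension (the GPLVM prior)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return rng.standard_normal((config.n, config.q))


def simulate_phenotype(config: SimulationConfig, g: np.ndarray | None,
                       donor: DonorDesign, X: np.ndarray | None = None, rng=None):
    """One phenotype draw; returns (y, truth dict with X and each component)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if X is None:
        X = rng.standard_normal((donor.Z.shape[0], config.q))
    X = np.atleast_2d(X)
    n = X.shape[0]
    K = add_jitter(eval_kernel(config.kernel, X, X))
    cK = np.linalg.cholesky(K)
    alpha = cK @ rng.standard_normal(n)
    eta = alpha.copy()
    truth = {"X": X, "alpha": alpha}
    if config.alpha0 != 0.0:
        eta += config.alpha0
    gamma = np.zeros(n)
    if config.delta_d > 0:
        sd = np.sqrt(config.delta_d)
        for idx in donor.groups:
            gamma[idx] = sd * (cK[np.ix_(idx, range(n))] @ rng.standard_normal(n))
    eta += gamma
    truth["gamma"] = gamma
    if config.delta_d0 > 0:
        g0 = np.sqrt(config.sigma2 * config.delta_d0) * rng.standard_normal(donor.n_donors)
        eta += donor.Z @ g0
    if g is not None:
        g = np.asarray(g, dtype=float)
        beta = np.zeros(n)
        if config.delta_g > 0:
            beta = np.sqrt(config.delta_g) * (cK @ rng.standard_normal(n))
        eta += config.beta0 * g + beta * g
        truth["beta"] = beta
    if config.family == "gaussian":
        y = eta + np.sqrt(config.sigma2) * rng.standard_normal(n)
    else:
        rate = np.exp(eta + config.log_mean_offset)
        y = rng.poisson(rate).astype(float)
        truth["rate"] = rate
    truth["eta"] = eta
    return y, truth


def simulate_expression(config: SimulationConfig, J: int, X: np.ndarray | None = None,
                        batch: np.ndarray | None = None, batch_sd: float = 0.0,
                        rng=None):
    """Gene-expression matrix Y (N x J) from independent GPs over shared X.

    Each gene j draws f_j ~ N(0, K) and adds N(0, sigma2) noise; an optional
    batch label adds a per-gene batch offset with standard deviation
    `batch_sd`.  Used to exercise the GPLVM.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if X is None:
        X = rng.standard_normal((config.n, config.q))
    X = np.atleast_2d(X)
    n = X.shape[0]
    K = add_jitter(eval_kernel(config.kernel, X, X))
    cK = np.linalg.cholesky(K)
    F = cK @ rng.standard_normal((n, J))
    Y = F + np.sqrt(config.sigma2) * rng.standard_normal((n, J))
    if batch is not None and batch_sd > 0:
        levels = np.unique(batch)
        offs = batch_sd * rng.standard_normal((len(levels), J))
        for li, lev in enumerate(levels):
            Y[batch == lev] += offs[li]
    return Y, {"X": X, "F": F}
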