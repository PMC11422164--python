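import numpy as np
import pytest

np.seterr(all="ignore")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_instance(rng):
    """A small random sparse-GP instance with donor structure."""
    from dyngp.kernels import KernelSpec
    from dyngp.sparse_gp import DonorDesign, build_factors

    n, m, n_d = 15, 4, 3
    X = rng.normal(size=(n, 2))
    T = rng.normal(size=(m, 2))
    spec = KernelSpec("ardse", variance=1.3, lengthscales=np.array([0.7, 1.5]))
    factors = build_factors(spec, X, T)
    donor = DonorDesign.from_assignment(rng.integers(0, n_d, size=n))
    y = rng.normal(size=n)
    g = rng.integers(0, 3, size=n).astype(float)
    return dict(n=n, m=m, X=X, T=T, spec=spec, factors=factors, donor=donor,
                y=y, g=g)
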