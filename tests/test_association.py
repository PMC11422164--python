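import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from dyngp.association import (
    estimate_kinship,
    fit_null,
    generalized_chi2_tail,
    genomic_inflation,
    log_bayes_factor,
    map_variants,
    qq_data,
    rank_inverse_normal,
    score_test,
)
from dyngp.kernels import KernelSpec
from dyngp.simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_phenotype,
    simulate_states,
)
from dyngp.sparse_gp import DonorDesign, LowRankCovariance, build_factors


class TestKinship:
    def test_single_variant_hand_computation(self):
        g = np.array([[0.0], [1.0], [2.0]])
        # p_hat = 0.5 -> centered (-1, 0, 1), scaled by sqrt(2*0.25) = sqrt(0.5)
        gt = np.array([-1.0, 0.0, 1.0]) / np.sqrt(0.5)
        expected = np.outer(gt, gt)
        assert np.allclose(estimate_kinship(g), expected)

    def test_identical_samples_have_self_similarity(self, rng):
        G = rng.integers(0, 3, size=(6, 40)).astype(float)
        G[3] = G[0]
        R = estimate_kinship(G)
        assert R[0, 3] == pytest.approx(R[0, 0], rel=1e-12)
        assert R[0, 3] == pytest.approx(R[3, 3], rel=1e-12)

    def test_unrelated_limit_many_variants(self, rng):
        # off-diagonals shrink to the finite-sample centering value -1/(N-1)
        # and the diagonal to ~1 as the variant count L grows
        n = 100
        G = rng.binomial(2, 0.3, size=(n, 10000)).astype(float)
        R = estimate_kinship(G)
        off = R[~np.eye(n, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1
        assert abs(off.mean() + 1.0 / (n - 1)) < 0.005
        assert np.allclose(np.diag(R), 1.0, atol=0.1)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            estimate_kinship(np.ones((5, 3)))


class TestGeneralizedChi2:
    @pytest.mark.parametrize("m", [1, 2, 4, 8])
    def test_unit_weights_reduce_to_central_chi2(self, m):
        for S in [0.5, 2.0, 8.0, 25.0]:
            p, _ = generalized_chi2_tail(S, np.ones(m))
            assert p == pytest.approx(chi2.sf(S, m), abs=1e-8)

    def test_singleton_weight_is_scaled_chi2(self):
        p, _ = generalized_chi2_tail(7.0, [2.5])
        assert p == pytest.approx(chi2.sf(7.0 / 2.5, 1), abs=1e-8)

    def test_monte_carlo_weights_two_one(self, rng):
        n = 10**6
        draws = 2.0 * rng.chisquare(1, n) + rng.chisquare(1, n)
        for S in [2.0, 6.0, 12.0]:
            mc = np.mean(draws > S)
            se = np.sqrt(mc * (1 - mc) / n)
            p, _ = generalized_chi2_tail(S, np.array([2.0, 1.0]))
            assert abs(p - mc) < 3 * se

    def test_far_tail_uses_saddlepoint_and_is_positive(self):
        p, method = generalized_chi2_tail(250.0, np.array([2.0, 1.0]))
        assert method == "saddlepoint"
        assert 0 < p < 1e-20

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generalized_chi2_tail(1.0, np.zeros(3))
        with pytest.raises(ValueError):
            generalized_chi2_tail(-1.0, np.ones(2))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_p_monotone_decreasing_in_s(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.1, 3.0, size=int(rng.integers(1, 6)))
        grid = np.linspace(0.1, 30, 12)
        ps = [generalized_chi2_tail(S, w)[0] for S in grid]
        assert np.all(np.diff(ps) < 0)


@pytest.fixture(scope="module")
def fitted_null():
    cfg = SimulationConfig(n_donors=12, cells_per_donor=8, seed=7)
    rng = np.random.default_rng(7)
    dos, donor, _, _ = simulate_genotypes(cfg, rng)
    X = simulate_states(cfg, rng)
    y, _ = simulate_phenotype(cfg, None, donor, X=X, rng=rng)
    yt = rank_inverse_normal(y)
    null = fit_null(yt, X, donor, m=6, seed=0, restarts=1)
    return yt, dos, donor, X, null


class TestScoreTest:
    def test_zero_genotype_gives_null_result(self, fitted_null):
        yt, dos, donor, X, null = fitted_null
        res = score_test(yt, np.zeros(len(yt)), null)
        assert res.score == 0.0
        assert res.p_value == 1.0

    def test_score_matches_dense_derivative_oracle(self, fitted_null, rng):
        """S equals y' Vd^-1 (dVg/d delta_g|0) Vd^-1 y computed densely."""
        yt, dos, donor, X, null = fitted_null
        g = dos[:, 0]
        res = score_test(yt, g, null)
        P = null.factors.phi @ null.factors.phi.T
        n = len(yt)
        Vd = (null.vc.sigma2 * np.eye(n) + P
              + null.vc.delta_d * P * (donor.Z @ donor.Z.T))
        vinv = np.linalg.solve(Vd, yt)
        G = np.diag(g)
        S_dense = float(vinv @ G @ P @ G @ vinv)
        assert res.score == pytest.approx(S_dense, rel=1e-8)

    def test_weights_match_nxn_similarity_oracle(self, fitted_null):
        yt, dos, donor, X, null = fitted_null
        g = dos[:, 1]
        res = score_test(yt, g, null)
        P = null.factors.phi @ null.factors.phi.T
        n = len(yt)
        Vd = (null.vc.sigma2 * np.eye(n) + P
              + null.vc.delta_d * P * (donor.Z @ donor.Z.T))
        G = np.diag(g)
        lam_n = np.sort(np.real(np.linalg.eigvals(
            G @ P @ G @ np.linalg.inv(Vd))))[::-1]
        lam = np.sort(res.weights)[::-1]
        assert np.allclose(lam, lam_n[: lam.size], rtol=1e-6,
                           atol=1e-8 * lam_n[0])

    def test_h2_bound_grid_matches_dense_oracle(self, fitted_null):
        from scipy.stats import multivariate_normal

        yt, dos, donor, X, null = fitted_null
        g = dos[:, 2]
        from dyngp.association import _bound_h2

        P = null.factors.phi @ null.factors.phi.T
        n = len(yt)
        kt = null.factors.ktilde_diag
        s2, dd = null.vc.sigma2, null.vc.delta_d
        Vd = s2 * np.eye(n) + P + dd * P * (donor.Z @ donor.Z.T)
        G = np.diag(g)
        for dg in (0.01, 0.1, 0.5):
            dense = (multivariate_normal.logpdf(yt, np.zeros(n), Vd + dg * G @ P @ G)
                     - ((1 + dd) * kt.sum() + dg * np.sum(g * g * kt)) / (2 * s2))
            assert _bound_h2(yt, null, g, dg) == pytest.approx(dense, rel=1e-8)


class TestBayesFactor:
    def test_zero_genotype_gives_exactly_zero(self, fitted_null):
        yt, dos, donor, X, null = fitted_null
        assert log_bayes_factor(yt, np.zeros(len(yt)), null) == 0.0

    def test_strong_dynamic_effect_gives_positive_log_bf(self):
        cfg = SimulationConfig(n_donors=15, cells_per_donor=10, delta_g=0.8,
                               maf_range=(0.3, 0.3), n_variants=1, seed=21)
        rng = np.random.default_rng(21)
        dos, donor, _, _ = simulate_genotypes(cfg, rng)
        X = simulate_states(cfg, rng)
        y, _ = simulate_phenotype(cfg, dos[:, 0], donor, X=X, rng=rng)
        yt = rank_inverse_normal(y)
        null = fit_null(yt, X, donor, m=8, seed=0, restarts=1)
        assert log_bayes_factor(yt, dos[:, 0], null) > 0


class TestMapVariants:
    def test_scan_completes_and_flags_monomorphic(self, fitted_null):
        yt, dos, donor, X, null = fitted_null
        G = dos[:, :10].copy()
        G[:, 4] = 1.0  # monomorphic
        df, _ = map_variants(yt, G, X, donor, transform=False, null=null)
        assert len(df) == 10
        tested = df[df["flag"] == ""]
        assert tested["p"].notna().all()
        assert df.loc[4, "flag"] == "skipped_monomorphic"
        assert np.isnan(df.loc[4, "p"])
        assert set(df.columns) >= {"variant", "score", "p", "fdr_bh"}
        assert (df.loc[tested.index, "fdr_bh"] >= df.loc[tested.index, "p"] - 1e-12).all()

    def test_spiked_causal_variant_ranks_first(self):
        cfg = SimulationConfig(n_donors=20, cells_per_donor=10, delta_g=0.8,
                               maf_range=(0.3, 0.3), n_variants=1, seed=3)
        rng = np.random.default_rng(3)
        dos, donor, _, _ = simulate_genotypes(cfg, rng)
        X = simulate_states(cfg, rng)
        y, _ = simulate_phenotype(cfg, dos[:, 0], donor, X=X, rng=rng)
        null_cfg = SimulationConfig(n_donors=20, cells_per_donor=10,
                                    n_variants=49, seed=4)
        nulls, _, _, _ = simulate_genotypes(null_cfg, np.random.default_rng(4))
        G = np.column_stack([dos[:, 0], nulls])
        df, _ = map_variants(y, G, X, donor, m=8, seed=0, restarts=1)
        tested = df[df["flag"] == ""]
        assert tested.sort_values("p").iloc[0]["variant"] == "v0"

    def test_misaligned_inputs_rejected(self, fitted_null):
        yt, dos, donor, X, null = fitted_null
        with pytest.raises(ValueError):
            map_variants(yt[:-1], dos, X, donor)


def test_rank_inverse_normal_properties(rng):
    y = rng.exponential(size=101)
    z = rank_inverse_normal(y)
    assert abs(z.mean()) < 0.05
    assert np.corrcoef(np.argsort(np.argsort(y)), np.argsort(np.argsort(z)))[0, 1] > 0.999999


def test_genomic_inflation_of_uniform_pvalues(rng):
    p = rng.uniform(size=200_000)
    assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)


def test_qq_data_shape_and_order(rng):
    out = qq_data(rng.uniform(size=50))
    assert out.shape == (50, 2)
    assert np.all(np.diff(out[:, 0]) <= 0) or np.all(np.diff(out[:, 0]) >= 0)
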