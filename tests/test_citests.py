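"""Conditional-independence statistics against closed-form oracles, null
calibration of the block-shuffle engine, and its contractual properties."""
import numpy as np
import pytest
from scipy import stats

import bgcausal as bg
from bgcausal.citests import (
    CITestOptions,
    block_shuffle_pvalue,
    ci_test,
    cmiknn,
    default_block_length,
    distance_correlation,
    gpdc,
    parcorr,
)


def partial_corr_precision_oracle(data: np.ndarray) -> float:
    """Partial correlation of columns 0 and 1 given the rest, from the inverse
    of the sample covariance matrix: -P01 / sqrt(P00 * P11)."""
    P = np.linalg.inv(np.cov(data.T))
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


OPT_FAST = CITestOptions(n_perm=99, seed=0)


class TestParcorr:
    def test_identical_series_statistic_one(self):
        x = np.random.default_rng(0).standard_normal(200)
        res = parcorr(x, x, options=OPT_FAST)
        assert res.statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("n_cond", [1, 2, 4])
    def test_matches_precision_matrix_oracle(self, n_cond):
        rng = np.random.default_rng(n_cond)
        data = rng.standard_normal((50, 2 + n_cond))
        res = parcorr(data[:, 0], data[:, 1], data[:, 2:], options=OPT_FAST)
        assert res.statistic == pytest.approx(
            partial_corr_precision_oracle(data), abs=1e-10
        )

    def test_gaussian_chain_conditionally_independent(self):
        # X -> Y -> Z: the partial correlation of (X, Z | Y) is exactly 0,
        # so the test should fail to reject in nearly all replicates
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.standard_normal(2_000)
            y = 0.8 * x + 0.6 * rng.standard_normal(2_000)
            z = 0.8 * y + 0.6 * rng.standard_normal(2_000)
            res = parcorr(x, z, y, options=CITestOptions(n_perm=199, seed=seed))
            hits += res.p_value > 0.01
        assert hits >= 19

    def test_analytic_pvalue_crosscheck(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        y = 0.3 * x + rng.standard_normal(500)
        res = parcorr(x, y, options=CITestOptions(n_perm=499, seed=1, analytic=True))
        assert res.p_analytic is not None
        assert res.p_analytic < 0.01 and res.p_value <= 0.01

    def test_rank_deficient_z_dropped(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 300))
        z = rng.standard_normal(300)
        Z = np.column_stack([z, 2 * z])  # duplicate direction
        res = parcorr(x, y, Z, options=OPT_FAST)
        assert "rank_deficient_Z_dropped" in res.flags
        ref = parcorr(x, y, z, options=OPT_FAST)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            parcorr(np.ones(8), np.ones(8), options=OPT_FAST)


class TestGPDC:
    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for seed in range(40):
            rng = np.random.default_rng(200 + seed)
            x, y = rng.standard_normal((2, 300))
            pvals.append(gpdc(x, y, options=CITestOptions(n_perm=99, seed=seed)).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_detects_quadratic_where_parcorr_does_not(self):
        # the rationale for the regression-based statistic: pure even
        # dependence has zero correlation but nonzero distance correlation
        hits_gpdc = hits_pc = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            x = rng.standard_normal(1_000)
            y = 0.25 * x**2 + rng.standard_normal(1_000)
            opt = CITestOptions(n_perm=199, seed=seed)
            hits_gpdc += gpdc(x, y, options=opt).p_value <= 0.01
            hits_pc += parcorr(x, y, options=opt).p_value <= 0.01
        assert hits_gpdc >= 8
        assert hits_pc <= 2

    def test_detects_linear_too(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(1_000)
        y = 0.8 * x + rng.standard_normal(1_000)
        assert gpdc(x, y, options=OPT_FAST).p_value <= 0.01

    def test_gp_residualization_removes_conditioner(self):
        # y depends on z non-linearly; after GP regression on z the residual
        # dependence with x (independent) should be undetected
        rng = np.random.default_rng(8)
        z = rng.standard_normal(400)
        x = np.tanh(z) + 0.3 * rng.standard_normal(400)
        y = z**2 + 0.3 * rng.standard_normal(400)
        res = gpdc(x, y, z, options=CITestOptions(n_perm=99, seed=2))
        assert res.p_value > 0.01


class TestCMIknn:
    def test_gaussian_mutual_information_closed_form(self):
        rho, n = 0.6, 4_000
        rng = np.random.default_rng(9)
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        res = cmiknn(x, y, options=CITestOptions(n_perm=99, seed=3))
        truth = -0.5 * np.log(1 - rho**2)
        assert res.statistic == pytest.approx(truth, abs=0.03)

    def test_independent_null(self):
        pvals = []
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            x, y = rng.standard_normal((2, 300))
            res = cmiknn(x, y, options=CITestOptions(n_perm=99, seed=seed))
            pvals.append(res.p_value)
            assert res.statistic < 0.1
        assert np.mean(np.asarray(pvals) <= 0.1) < 0.35  # roughly uniform

    def test_conditional_independence_with_local_permutation(self):
        # x and y both driven by z, independent given z
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            z = rng.standard_normal(600)
            x = 0.8 * z + 0.6 * rng.standard_normal(600)
            y = 0.8 * z + 0.6 * rng.standard_normal(600)
            res = cmiknn(x, y, z, options=CITestOptions(n_perm=99, seed=seed))
            hits += res.p_value > 0.01
        assert hits >= 8

    def test_multiplicative_noise_detected(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(2_000)
        y = x * rng.standard_normal(2_000)
        res = cmiknn(x, y, options=CITestOptions(n_perm=99, seed=4))
        assert res.p_value <= 0.01

    def test_small_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            cmiknn(np.ones(100), np.ones(100), options=CITestOptions(k=2))

    def test_duplicate_points_jittered(self):
        x = np.repeat([0.0, 1.0], 100)
        y = np.repeat([1.0, 0.0], 100)
        res = cmiknn(x, y, options=CITestOptions(n_perm=99, seed=5))
        assert "tie_jitter" in res.flags


class TestBlockShuffleEngine:
    def test_extreme_observed_statistic_min_p(self):
        # observed statistic above every permuted one -> p = 1/(n_perm + 1)
        x = np.arange(400, dtype=float)
        y = x.copy()
        p = block_shuffle_pvalue(
            lambda a, b, Z: np.corrcoef(a, b)[0, 1], x, y,
            n_perm=99, block_len=10, seed=0,
        )
        assert p == pytest.approx(1 / 100)

    def test_null_rejection_rate_calibrated(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(600 + seed)
            x, y = rng.standard_normal((2, 250))
            p = parcorr(x, y, options=CITestOptions(n_perm=99, seed=seed)).p_value
            hits += p <= 0.05
        lo, hi = stats.binom.interval(0.999, n_seeds, 0.05)
        assert lo <= hits <= hi

    def test_autocorrelated_null_needs_blocks(self):
        """With strongly autocorrelated but independent channels, single-sample
        shuffling over-rejects while the autocorrelation-matched block length
        keeps the level near nominal."""
        from bgcausal.synthdata import generate_block
        from bgcausal import RegionSet

        regions = RegionSet(("X", "Y"))
        hits_auto = hits_single = 0
        n_seeds = 60
        for seed in range(n_seeds):
            blk = generate_block(regions, [], 400, autocorr=0.9, seed=700 + seed)
            x, y = blk[:, 0], blk[:, 1]
            p_auto = parcorr(x, y, options=CITestOptions(n_perm=99, seed=seed)).p_value
            p_single = parcorr(
                x, y, options=CITestOptions(n_perm=99, seed=seed, block_len=1)
            ).p_value
            hits_auto += p_auto <= 0.05
            hits_single += p_single <= 0.05
        # single-sample shuffle badly over-rejects at autocorr 0.9
        assert hits_single > hits_auto
        assert hits_single / n_seeds > 0.2
        lo, hi = stats.binom.interval(0.999, n_seeds, 0.05)
        assert hits_auto <= hi + 2  # near-nominal with matched blocks

    def test_block_len_too_large_rejected(self):
        x = np.random.default_rng(0).standard_normal(100)
        with pytest.raises(ValueError, match="block_len"):
            parcorr(x, x, options=CITestOptions(n_perm=99, block_len=30))

    def test_n_perm_floor(self):
        x = np.arange(100.0)
        with pytest.raises(ValueError, match="n_perm"):
            block_shuffle_pvalue(lambda a, b, Z: 0.0, x, x, n_perm=10, block_len=5)

    def test_monotone_permutation_contract(self):
        """Raising the observed statistic's magnitude with the permutation draws
        fixed can never raise the p-value."""
        rng = np.random.default_rng(11)
        perm_stats = rng.standard_normal(199)

        def p_of(obs):
            return (1 + np.sum(np.abs(perm_stats) >= abs(obs))) / 200

        grid = np.linspace(0, 3, 50)
        ps = [p_of(v) for v in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_default_block_length_rule(self):
        from bgcausal.synthdata import generate_block
        from bgcausal import RegionSet

        regions = RegionSet(("X",))
        white = generate_block(regions, [], 2_000, autocorr=0.0, seed=1)[:, 0]
        assert default_block_length([white], len(white)) <= 2
        sticky = generate_block(regions, [], 2_000, autocorr=0.9, seed=2)[:, 0]
        assert default_block_length([sticky], len(sticky)) > 5
        # clamped to n/20
        assert default_block_length([sticky], len(sticky)) <= 100

    def test_boundaries_respected(self):
        # blocks must never straddle a concatenation boundary
        from bgcausal.citests import _index_blocks

        blocks = _index_blocks(20, 3, boundaries=(0, 10))
        for b in blocks:
            assert (b < 10).all() or (b >= 10).all()
        assert sorted(np.concatenate(blocks).tolist()) == list(range(20))


class TestSymmetryAndDispatcher:
    @pytest.mark.parametrize("method", ["PC", "GPDC", "CMIknn"])
    def test_lag0_statistic_symmetric(self, method):
        rng = np.random.default_rng(12)
        z = rng.standard_normal(300)
        x = 0.5 * z + rng.standard_normal(300)
        y = 0.5 * z + rng.standard_normal(300)
        opt = CITestOptions(n_perm=99, seed=6)
        s_xy = ci_test(method, x, y, z, opt).statistic
        s_yx = ci_test(method, y, x, z, opt).statistic
        assert s_xy == pytest.approx(s_yx, abs=1e-9)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown CI method"):
            ci_test("tau", np.ones(50), np.ones(50))

    def test_disk_cache_roundtrip(self, tmp_path):
        rng = np.random.default_rng(13)
        x, y = rng.standard_normal((2, 300))
        opt = CITestOptions(n_perm=99, seed=7, cache_dir=str(tmp_path))
        r1 = ci_test("CMIknn", x, y, None, opt)
        assert list(tmp_path.glob("*.json"))
        r2 = ci_test("CMIknn", x, y, None, opt)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)

    def test_distance_correlation_perfect_dependence(self):
        x = np.linspace(-1, 1, 100)
        assert distance_correlation(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-10)
        rng = np.random.default_rng(14)
        a, b = rng.standard_normal((2, 500))
        assert distance_correlation(a, b) < 0.15
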