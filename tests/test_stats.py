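"""Spatial statistics: BH-FDR, permutation tests, Hedges's g, McNemar,
and the voxelwise paired-t map."""

import numpy as np
import pytest
from scipy import stats as sps

from enlfc import stats
from enlfc.errors import (
    ContractError,
    DomainError,
    InsufficientSampleError,
    ParameterError,
    UndefinedTestError,
)


class TestBhFdr:
    def test_hand_enumerated_step_up(self):
        p = np.array([0.01, 0.02, 0.04, 0.05, 0.2])
        m = 5
        raw = p * m / np.arange(1, 6)  # already sorted
        expected = np.minimum.accumulate(raw[::-1])[::-1]
        assert np.allclose(stats.bh_fdr(p), np.minimum(expected, 1.0), atol=1e-14)

    def test_edge_cases_and_monotonicity(self, rng):
        assert np.all(stats.bh_fdr(np.ones(7)) == 1.0)
        assert stats.bh_fdr(np.array([0.031]))[0] == pytest.approx(0.031)
        p = rng.uniform(size=100)
        q = stats.bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        # order preserved: shuffling input shuffles output identically
        perm = rng.permutation(100)
        assert np.allclose(stats.bh_fdr(p[perm]), q[perm], atol=1e-14)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            stats.bh_fdr(np.array([0.5, 1.2]))


class TestPermutation:
    def test_degenerate_identical_pairs(self):
        a = np.arange(6.0)
        p, obs = stats.permutation_test(a, a, "paired", n_perm=200, seed=0)
        assert obs == 0.0 and p == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        d = a - b
        signs = (np.arange(2**8)[:, None] >> np.arange(8)) & 1
        null = ((2.0 * signs - 1.0) * d).mean(axis=1)
        expected = float(np.mean(np.abs(null) >= abs(d.mean()) - 1e-15))
        p_ex, _ = stats.permutation_test(a, b, "paired", exhaustive=True)
        assert p_ex == pytest.approx(expected, abs=1e-15)
        p_mc, _ = stats.permutation_test(a, b, "paired", n_perm=20000, seed=1)
        assert p_mc == pytest.approx(expected, abs=0.02)

    def test_resolution_floor_under_huge_separation(self):
        # 20 pairs: the chance of resampling the identity/antipodal sign
        # pattern among 999 draws is negligible, so p hits the floor
        a = np.full(20, 100.0) + np.arange(20) * 0.01
        b = np.zeros(20)
        p, _ = stats.permutation_test(a, b, "paired", n_perm=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_independent_design_null_calibration(self, rng):
        # Type-I error at alpha=.05 under an exchangeable null
        hits = 0
        n_sim = 400
        for i in range(n_sim):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            p, _ = stats.permutation_test(a, b, "independent", n_perm=199, seed=rng)
            hits += p < 0.05
        rate = hits / n_sim
        assert 0.02 < rate < 0.09

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            stats.permutation_test([1, 2], [1, 2], n_perm=0)
        with pytest.raises(ContractError):
            stats.permutation_test([1.0], [], "independent")


class TestHedgesG:
    def test_null_and_antisymmetry(self, rng):
        a = rng.normal(size=20)
        assert stats.hedges_g(a, a, "paired").hedges_g == 0.0
        b = rng.normal(size=25)
        g1 = stats.hedges_g(a, b, "independent")
        g2 = stats.hedges_g(b, a, "independent")
        assert g1.hedges_g == pytest.approx(-g2.hedges_g)
        assert np.sign(g1.hedges_g) == np.sign(g1.difference)

    def test_small_sample_correction_factor(self, rng):
        # g = J * d with J = 1 - 3/(4 df - 1); df=98 gives J ~ 0.99233
        a = rng.normal(0, 1, size=50)
        b = rng.normal(1, 1, size=50)
        df = 98
        sp = np.sqrt(((49) * a.var(ddof=1) + (49) * b.var(ddof=1)) / df)
        d = (a.mean() - b.mean()) / sp
        J = 1 - 3 / (4 * df - 1)
        assert stats.hedges_g(a, b, "independent").hedges_g == pytest.approx(J * d, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(ContractError):
            stats.hedges_g(np.full(5, 1.0), np.full(5, 2.0), "independent")


class TestMcnemar:
    def test_closed_forms(self):
        chi2, p, odds = stats.mcnemar_test(100, 15, 5, 80)
        assert chi2 == pytest.approx((10 - 1) ** 2 / 20)  # = 4.05
        assert p == pytest.approx(2 * sps.binom.cdf(5, 20, 0.5), abs=1e-12)
        assert odds == pytest.approx(3.0)

    def test_cross_check_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = [[100, 15], [5, 80]]
        ours = stats.mcnemar_test(100, 15, 5, 80)
        theirs = sm_mcnemar(table, exact=True)
        assert ours[1] == pytest.approx(theirs.pvalue, abs=1e-10)
        big = stats.mcnemar_test(0, 40, 20, 0)
        theirs_chi2 = sm_mcnemar([[0, 40], [20, 0]], exact=False, correction=True)
        assert big[0] == pytest.approx(theirs_chi2.statistic, abs=1e-10)

    def test_symmetric_and_degenerate(self):
        chi2, p, odds = stats.mcnemar_test(10, 7, 7, 10)
        assert odds == 1.0 and p > 0.9
        with pytest.raises(UndefinedTestError):
            stats.mcnemar_test(5, 0, 0, 5)
        assert stats.mcnemar_test(0, 3, 0, 0)[2] == float("inf")


class TestPairedTMap:
    def test_null_identity(self, rng):
        a = rng.normal(size=(10, 30))
        res = stats.paired_t_map_fdr(a, a.copy(), np.ones(30, bool))
        assert np.all(res.statistic[res.test_mask] == 0)
        assert not res.significant.any()

    def test_large_shift_all_significant(self, rng):
        a = rng.normal(size=(30, 40))
        res = stats.paired_t_map_fdr(a + 10, a, np.ones(40, bool))
        assert res.significant.all()

    def test_matches_scalar_scipy_loop(self, rng):
        a = rng.normal(size=(12, 15))
        b = rng.normal(size=(12, 15))
        res = stats.paired_t_map_fdr(a, b, np.ones(15, bool))
        for j in range(15):
            t, p = sps.ttest_rel(a[:, j], b[:, j])
            assert res.statistic[j] == pytest.approx(t, abs=1e-10)
            assert res.p[j] == pytest.approx(p, abs=1e-10)

    def test_mask_and_sample_errors(self, rng):
        a = rng.normal(size=(10, 5))
        with pytest.raises(ContractError):
            stats.paired_t_map_fdr(a, a, np.zeros(5, bool))
        with pytest.raises(InsufficientSampleError):
            stats.paired_t_map_fdr(a[:2], a[:2], np.ones(5, bool))

    def test_agrees_with_sign_flip_permutation_map(self, rng):
        # hypothesis-map agreement between parametric and permutation routes
        n, v = 24, 60
        a = rng.normal(size=(n, v))
        b = rng.normal(size=(n, v))
        b[:, :20] += 1.6  # decisive planted differences in a third of voxels
        res = stats.paired_t_map_fdr(a, b, np.ones(v, bool))
        perm_p = np.array([
            stats.permutation_test(a[:, j], b[:, j], "paired", n_perm=999, seed=rng)[0]
            for j in range(v)
        ])
        rho = np.corrcoef(res.significant, stats.bh_fdr(perm_p) < 0.05)[0, 1]
        assert rho > 0.9


def test_supra_threshold_union():
    za = np.array([0.0, 2.5, -2.5, 1.0])
    zb = np.array([0.0, 0.0, 0.0, 2.2])
    assert list(stats.supra_threshold_union(za, zb)) == [False, True, True, True]
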