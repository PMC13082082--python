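"""FC estimation: Z-scoring, Pearson, U-centering, bias-corrected distance
correlation, the Gaussian null, and the ENL decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enlfc import fc
from enlfc.errors import ContractError, DegenerateVoxelError, DomainError, SampleSizeError

from conftest import naive_dcor_sq, naive_u_centered


class TestZscore:
    def test_definition_and_idempotence(self):
        ts = fc.zscore_timeseries(np.array([[1.0], [2.0], [3.0], [4.0]]))
        assert abs(ts.values.mean()) < 1e-12
        assert abs(ts.values.std(ddof=1) - 1) < 1e-12
        again = fc.zscore_timeseries(ts.values)
        assert np.allclose(again.values, ts.values, atol=1e-12)

    def test_constant_column_rejected_with_voxel_index(self):
        raw = np.column_stack([np.arange(5.0), np.full(5, 5.0)])
        with pytest.raises(DegenerateVoxelError) as exc:
            fc.zscore_timeseries(raw)
        assert exc.value.voxel == 1

    def test_too_few_timepoints(self):
        with pytest.raises(SampleSizeError):
            fc.zscore_timeseries(np.random.default_rng(0).normal(size=(3, 2)))


class TestPearson:
    def test_self_and_sign_flip(self, rng):
        x = rng.normal(size=50)
        ts = fc.zscore_timeseries(np.column_stack([x, x, -x]))
        r = fc.pearson_fc(ts).values
        assert r[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert r[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_covariance_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 3, 2, 5, 4])
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        expected = sum(a * b for a, b in zip(zx, zy)) / (len(x) - 1)
        ts = fc.zscore_timeseries(np.column_stack([x, y]))
        assert fc.pearson_fc(ts).values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_normalized_input(self, rng):
        ts = fc.TimeSeriesMatrix(values=rng.normal(size=(20, 3)) * 5)
        with pytest.raises(ContractError):
            fc.pearson_fc(ts)


class TestUCentering:
    def test_matches_four_term_loop_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        A = fc.u_centered_distances(x).matrix
        assert np.allclose(A, naive_u_centered(x), atol=1e-12)

    def test_affine_homogeneity(self, rng):
        x = rng.normal(size=12)
        A = fc.u_centered_distances(x).matrix
        A2 = fc.u_centered_distances(2 * x + 3).matrix
        assert np.allclose(A2, 2 * A, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=40))
    def test_zero_diagonal_and_margins(self, xs):
        A = fc.u_centered_distances(np.array(xs)).matrix
        n = A.shape[0]
        assert np.all(np.diag(A) == 0)
        assert np.abs(A.sum(axis=0)).max() < 1e-9 * n * (1 + np.abs(xs).max())
        assert np.abs(A.sum(axis=1)).max() < 1e-9 * n * (1 + np.abs(xs).max())

    def test_sample_size_error(self):
        with pytest.raises(SampleSizeError):
            fc.u_centered_distances(np.array([1.0, 2.0, 3.0]))


class TestBiasCorrectedDcor:
    def test_self_dependence_is_one(self, rng):
        x = rng.normal(size=30)
        assert fc.bias_corrected_dcor_sq(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        x = np.array([0.0, 1, 2, 3, 5, 8])
        y = np.array([2.0, 1, 0, 4, 3, 7])
        assert fc.bias_corrected_dcor_sq(x, y) == pytest.approx(naive_dcor_sq(x, y), abs=1e-12)

    def test_streaming_kernel_matches_matrix_path(self, rng, monkeypatch):
        x = rng.normal(size=500)
        y = 0.4 * x + rng.normal(size=500)
        small = fc.bias_corrected_dcor_sq(x, y)
        monkeypatch.setattr(fc, "_STREAM_N", 100)  # force the numba streaming path
        streamed = fc.bias_corrected_dcor_sq(x, y)
        assert streamed == pytest.approx(small, abs=1e-10)

    def test_mean_zero_under_independence(self, rng):
        vals = [
            fc.bias_corrected_dcor_sq(rng.standard_normal(50), rng.standard_normal(50))
            for _ in range(400)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    def test_degenerate_series(self, rng):
        with pytest.raises(DegenerateVoxelError):
            fc.bias_corrected_dcor_sq(np.full(10, 2.0), rng.normal(size=10))


class TestNLMatrix:
    def test_vectorized_equals_pairwise_loop(self, rng):
        ts = fc.zscore_timeseries(rng.normal(size=(60, 20)))
        nl = fc.nl_fc_matrix(ts, block_size=7).values
        for i in range(0, 20, 5):
            for j in range(i + 1, 20, 4):
                r2 = fc.bias_corrected_dcor_sq(ts.values[:, i], ts.values[:, j])
                assert nl[i, j] == pytest.approx(np.sqrt(max(r2, 0.0)), abs=1e-10)
        assert np.allclose(np.diag(nl), 1.0)

    def test_truncation_and_duplicates(self, rng):
        x = rng.normal(size=40)
        ts = fc.zscore_timeseries(np.column_stack([x, x, rng.normal(size=40)]))
        nl = fc.nl_fc_matrix(ts).values
        assert nl[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert nl.min() >= 0.0


class TestGaussianNull:
    def test_analytic_endpoints(self):
        assert fc.gaussian_null_value(0.0) == 0.0
        assert fc.gaussian_null_value(1.0) == pytest.approx(1.0, abs=1e-12)
        assert fc.gaussian_null_value(-1.0) == pytest.approx(1.0, abs=1e-12)

    def test_even_and_monotone(self):
        r = np.linspace(0, 1, 101)
        vals = fc.gaussian_null_value(r)
        assert np.allclose(fc.gaussian_null_value(-r), vals, atol=1e-14)
        assert np.all(np.diff(vals) >= -1e-14)
        assert vals.min() >= 0 and vals.max() <= 1

    def test_domain_error(self):
        with pytest.raises(DomainError):
            fc.gaussian_null_value(1.001)

    def test_matches_empirical_bivariate_normal(self, rng):
        # closed form vs the empirical sqrt-truncated estimator at rho=0.5
        n = 20000
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        emp = np.sqrt(max(fc.bias_corrected_dcor_sq(z[:, 0], z[:, 1]), 0))
        assert emp == pytest.approx(fc.gaussian_null_value(0.5), abs=0.02)


class TestENLDecomposition:
    def test_subtraction_identity_and_kinds(self, rng):
        ts = fc.zscore_timeseries(rng.normal(size=(50, 8)))
        lin, nl, null, enl = fc.enl_fc_matrix(ts)
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(enl.values[off], (nl.values - null.values)[off], atol=1e-14)
        assert np.all(np.diag(enl.values) == 0)
        for m in (lin, nl, null, enl):
            m.validate()

    def test_quadratic_pair_is_enl_only(self):
        # local generator: the |r| < .05 bound is tight enough that the
        # draw must not depend on test execution order
        rng = np.random.default_rng(99)
        x = rng.standard_normal(2000)
        y = x**2 + 0.1 * rng.standard_normal(2000)
        ts = fc.zscore_timeseries(np.column_stack([x, y]))
        lin, _nl, _null, enl = fc.enl_fc_matrix(ts)
        assert abs(lin.values[0, 1]) < 0.05
        assert enl.values[0, 1] > 0.2
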