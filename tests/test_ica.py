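"""Connectivity-domain ICA: PCA stages, Infomax, ICASSO stability,
network classification/matching, and GIG-ICA back-reconstruction."""

import numpy as np
import pytest

from enlfc import ica
from enlfc.errors import AlignmentError, ParameterError


def planted_mixture(rng, k=5, v=5000):
    S = rng.laplace(size=(k, v))
    A = rng.standard_normal((k, k))
    return S, A @ S


def best_abs_corr(truth, est):
    C = np.abs(np.corrcoef(np.vstack([truth, est]))[: truth.shape[0], truth.shape[0] :])
    return C.max(axis=1)


class TestScanPCA:
    def test_exact_low_rank_recovery(self, rng):
        W = rng.normal(size=(100, 3))
        M = W @ W.T
        basis = ica.scan_level_pca(M, k=3)
        recon = basis.scores @ basis.loadings.T + basis.mean
        assert np.abs(recon - M).max() < 1e-8

    def test_variance_ordering_and_linearity(self, rng):
        M = rng.normal(size=(80, 80))
        M = M @ M.T / 80
        b1 = ica.scan_level_pca(M, k=10)
        b1.validate()
        assert np.all(np.diff(b1.explained_variance) <= 1e-10)
        b2 = ica.scan_level_pca(2 * M, k=10)
        # doubling the matrix: same directions, variances x4
        assert np.allclose(np.abs(b2.loadings.T @ b1.loadings), np.eye(10), atol=1e-6)
        assert np.allclose(b2.explained_variance, 4 * b1.explained_variance, rtol=1e-8)

    def test_k_too_large(self, rng):
        M = np.eye(10)
        with pytest.raises(ParameterError):
            ica.scan_level_pca(M, k=10)


class TestGroupPCA:
    def test_identical_scans_span_single_scan_subspace(self, rng):
        M = rng.normal(size=(60, 60))
        M = M @ M.T / 60
        scan = ica.scan_level_pca(M, k=8)
        group = ica.group_pca([scan] * 4, k=8)
        # principal angles between the two 8-dim score subspaces ~ 0
        qa, _ = np.linalg.qr(scan.scores)
        qb, _ = np.linalg.qr(group.scores)
        sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
        assert np.all(sv > 1 - 1e-6)

    def test_disjoint_subspaces_both_captured(self, rng):
        v = 100
        u1 = np.zeros((v, 1)); u1[:30, 0] = rng.normal(size=30)
        u2 = np.zeros((v, 1)); u2[60:, 0] = rng.normal(size=40)
        m1 = u1 @ u1.T + 1e-3 * np.eye(v)
        m2 = u2 @ u2.T + 1e-3 * np.eye(v)
        bases = [ica.scan_level_pca(m, k=5) for m in (m1, m2)]
        group = ica.group_pca(bases, k=4)
        q, _ = np.linalg.qr(group.scores)
        for u in (u1, u2):
            proj = np.linalg.norm(q.T @ (u / np.linalg.norm(u)))
            assert proj > 0.97  # slightly below 1 because PCA centers features

    def test_contract(self, rng):
        M = rng.normal(size=(50, 50)); M = M @ M.T
        b = ica.scan_level_pca(M, k=25)
        assert ica.group_pca([b, b], k=20).k == 20
        other = ica.scan_level_pca(np.eye(40), k=5)
        with pytest.raises(AlignmentError):
            ica.group_pca([b, other], k=4)


class TestInfomax:
    def test_unmixed_input_stays_unmixed(self, rng):
        S = rng.laplace(size=(4, 4000))
        run = ica.infomax_ica(S, seed=1)
        # Amari-style check: unmixing ~ scaled signed permutation of identity
        P = np.abs(run["unmixing"] @ np.cov(S) @ run["unmixing"].T)
        P = P / P.max(axis=1, keepdims=True)
        assert np.all((P > 0.95).sum(axis=1) == 1)

    def test_planted_source_recovery(self, rng):
        S, X = planted_mixture(rng)
        rec = ica.infomax_ica(X, seed=3)["sources"]
        assert best_abs_corr(S, rec).min() > 0.95

    def test_determinism(self, rng):
        _, X = planted_mixture(rng)
        a = ica.infomax_ica(X, seed=11)
        b = ica.infomax_ica(X, seed=11)
        assert np.array_equal(a["sources"], b["sources"])


class TestIcasso:
    def test_identical_runs_give_unit_iq(self, rng):
        # orthogonal sources, no mixing, no bootstrap: every run recovers the
        # same components, intra-similarity 1 and extra-similarity ~ 0
        S = rng.laplace(size=(4, 4000))
        S, _ = np.linalg.qr(S.T, mode="reduced")
        S = (S / S.std(axis=0, ddof=1)).T
        res = ica.icasso(S, n_runs=5, model_order=4, seed=0, bootstrap=False)
        assert np.all(res.iq > 0.98)

    def test_planted_sources_beat_noise(self, rng):
        S, X = planted_mixture(rng)
        strong = ica.icasso(X, n_runs=10, model_order=5, seed=2)
        noise = ica.icasso(rng.standard_normal((5, 5000)), n_runs=10, model_order=5, seed=2)
        assert strong.iq.min() > 0.8
        assert np.median(noise.iq) < np.median(strong.iq)
        cs = ica.components_from_icasso(strong, X)
        assert best_abs_corr(S, cs.z_maps).min() > 0.9

    def test_determinism_under_master_seed(self, rng):
        _, X = planted_mixture(rng, k=3, v=2000)
        a = ica.icasso(X, n_runs=4, model_order=3, seed=5)
        b = ica.icasso(X, n_runs=4, model_order=3, seed=5)
        assert np.array_equal(a.centrotypes, b.centrotypes)
        assert np.array_equal(a.iq, b.iq)


def make_component_set(maps, branch="ENL"):
    z = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, ddof=1, keepdims=True)
    flip = np.sign(z[np.arange(z.shape[0]), np.abs(z).argmax(axis=1)])
    z = z * flip[:, None]
    return ica.ComponentSet(spatial_maps=maps, z_maps=z, mixing=np.eye(maps.shape[0]),
                            model_order=maps.shape[0], branch=branch)


class FakeIcasso:
    def __init__(self, iq):
        self.iq = np.asarray(iq, dtype=float)


class TestClassification:
    def setup_method(self):
        rng = np.random.default_rng(4)
        v = 100
        maps = np.zeros((3, v))
        maps[0, :20] = 5.0   # peak + overlap inside mask
        maps[1, 80:] = 5.0   # peak outside mask
        maps[2, :20] = 5.0   # good map, low IQ
        maps += 0.1 * rng.normal(size=(3, v))
        self.cs = make_component_set(maps)
        self.mask = np.zeros(v, dtype=bool)
        self.mask[:50] = True

    def test_all_three_criteria(self):
        table = ica.classify_components(self.cs, FakeIcasso([0.95, 0.95, 0.79]), self.mask)
        assert list(table.is_network) == [True, False, False]
        assert table.rejection_reason[1] == "peak outside gray matter"
        assert "IQ" in table.rejection_reason[2]

    def test_iq_threshold_is_strict(self):
        table = ica.classify_components(self.cs, FakeIcasso([0.80, 0.95, 0.95]), self.mask)
        assert not table.is_network[0]  # IQ must exceed .80, not equal it


class TestGreedyMatch:
    def test_identical_sets_self_match(self, rng):
        maps = rng.normal(size=(3, 200))
        cs = make_component_set(maps)
        table = ica.NetworkLabelTable(np.ones(3, bool), ["a", "b", "c"], [None] * 3)
        m = ica.greedy_match_networks(cs, cs, table, table)
        assert all(r == pytest.approx(1.0) for _, _, r in m.pairs)
        assert all(m.concordant)

    def test_constructed_cross_correlations(self, rng):
        base = rng.normal(size=(3, 500))

        def noisy(x, r):
            # construct a map correlating with x at ~r
            noise = rng.normal(size=x.shape)
            noise -= noise @ x / (x @ x) * x
            return r * x / np.linalg.norm(x) + np.sqrt(1 - r**2) * noise / np.linalg.norm(noise)

        enl = make_component_set(base)
        lin = make_component_set(np.vstack([noisy(base[0], 0.95), noisy(base[1], 0.85), noisy(base[2], 0.40)]))
        t = ica.NetworkLabelTable(np.ones(3, bool), [None] * 3, [None] * 3)
        m = ica.greedy_match_networks(enl, lin, t, t)
        assert m.concordant[0] and m.concordant[1]
        assert not m.concordant[2]
        assert 2 in m.unique_enl and 2 in m.unique_lin

    def test_tie_break_lowest_indices(self):
        maps = np.vstack([np.sin(np.linspace(0, 7, 300)), np.cos(np.linspace(0, 7, 300))])
        enl = make_component_set(maps)
        lin = make_component_set(maps.copy())
        t = ica.NetworkLabelTable(np.ones(2, bool), [None] * 2, [None] * 2)
        m = ica.greedy_match_networks(enl, lin, t, t)
        assert m.pairs[0][:2] == (0, 0)
        assert m.pairs[1][:2] == (1, 1)

    def test_empty_set_warns(self, rng):
        cs = make_component_set(rng.normal(size=(2, 100)))
        empty = ica.NetworkLabelTable(np.zeros(2, bool), [None] * 2, ["x"] * 2)
        full = ica.NetworkLabelTable(np.ones(2, bool), [None] * 2, [None] * 2)
        with pytest.warns(UserWarning):
            m = ica.greedy_match_networks(cs, cs, empty, full)
        assert m.pairs == [] and m.unique_lin == [0, 1]


class TestGIG:
    def test_identity_scan_reproduces_references(self, rng):
        v, k = 300, 6
        maps = rng.laplace(size=(k, v))
        group = make_component_set(maps)
        scores = maps.T @ rng.standard_normal((k, k))  # scan subspace = group subspace
        stack = ica.gig_backreconstruct(group, scores)
        for c in range(k):
            r = abs(np.corrcoef(stack.maps[0, c], group.z_maps[c])[0, 1])
            assert r > 0.99

    def test_recovers_participant_specific_perturbation(self, rng):
        v, k = 400, 5
        group_maps = rng.laplace(size=(k, v))
        group = make_component_set(group_maps)
        pert = group_maps + 0.35 * rng.laplace(size=(k, v))  # participant truth
        scores = pert.T  # scan subspace spanned by participant-specific maps
        stack = ica.gig_backreconstruct(group, scores)
        for c in range(k):
            r_part = abs(np.corrcoef(stack.maps[0, c], pert[c])[0, 1])
            r_group_vs_part = abs(np.corrcoef(group.z_maps[c], pert[c])[0, 1])
            assert r_part > r_group_vs_part

    def test_voxel_permutation_equivariance(self, rng):
        v, k = 200, 4
        maps = rng.laplace(size=(k, v))
        group = make_component_set(maps)
        scores = maps.T + 0.1 * rng.normal(size=(v, k))
        perm = rng.permutation(v)
        a = ica.gig_backreconstruct(group, scores)
        gp = make_component_set(maps[:, perm])
        b = ica.gig_backreconstruct(gp, scores[perm])
        assert np.allclose(a.maps[0][:, perm], b.maps[0], atol=1e-6)
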