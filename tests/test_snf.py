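"""Affinity kernel contracts, diffusion fusion, spectral clustering and
eigengap selection, and the covering edge-list export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snfomics import (
    SNFParams,
    build_affinity,
    estimate_num_clusters,
    export_network,
    fuse_networks,
    spectral_cluster,
)

from conftest import make_matrix


def _blob_matrix(rng, n_per=3, sep=6.0, n_features=20):
    a = rng.normal(0, 1, size=(n_features, n_per))
    b = rng.normal(sep, 1, size=(n_features, n_per))
    return make_matrix(np.hstack([a, b]))


def _block_similarity(n=8, inner=0.8, outer=0.1):
    W = np.full((n, n), outer)
    h = n // 2
    W[:h, :h] = inner
    W[h:, h:] = inner
    np.fill_diagonal(W, 1.0)
    return W


class TestBuildAffinity:
    def test_identical_samples_have_unit_affinity(self):
        vals = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0], [0.0, 0.0, 4.0]])
        aff = build_affinity(make_matrix(vals), SNFParams(K=1))
        assert aff.W[0, 1] == pytest.approx(1.0)

    def test_p_and_s_normalisation(self):
        rng = np.random.default_rng(0)
        aff = build_affinity(make_matrix(rng.normal(size=(30, 9))), SNFParams(K=3))
        assert np.allclose(aff.P.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(np.diag(aff.P), 0.5)
        assert np.allclose(aff.S.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(aff.W, aff.W.T, atol=1e-9)
        assert np.allclose(np.diag(aff.W), aff.W.max(axis=1))

    def test_blob_structure_reflected(self):
        rng = np.random.default_rng(1)
        aff = build_affinity(_blob_matrix(rng), SNFParams(K=2))
        W = aff.W
        within = np.r_[W[:3, :3][np.triu_indices(3, 1)], W[3:, 3:][np.triu_indices(3, 1)]]
        between = W[:3, 3:].ravel()
        assert within.mean() > between.mean()

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="K"):
            build_affinity(make_matrix(rng.normal(size=(5, 4))), SNFParams(K=4))

    def test_missing_values_rejected(self):
        vals = np.ones((3, 4))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_affinity(make_matrix(vals), SNFParams(K=2))


class TestFuseNetworks:
    def test_t_zero_is_average_of_p(self):
        rng = np.random.default_rng(3)
        a = build_affinity(make_matrix(rng.normal(size=(20, 8))), SNFParams(K=3, T=0))
        b = build_affinity(make_matrix(rng.normal(size=(20, 8)), layer="protein"), SNFParams(K=3, T=0))
        fused = fuse_networks([a, b], SNFParams(K=3, T=0)).fused
        avg = (a.P + b.P) / 2
        assert np.allclose(fused, (avg + avg.T) / 2, atol=1e-12)  # symmetrised average

    def test_self_fusion_preserves_strong_ordering(self):
        """Fusing a layer with its own copy keeps the similarity ordering
        close to that layer's P. Diffusion through the KNN kernel reorders
        weak similarities, so the rank correlation is high but not exactly
        1 at T > 0 (it is exactly 1 at T = 0, covered above)."""
        rng = np.random.default_rng(4)
        a = build_affinity(_blob_matrix(rng, n_per=5), SNFParams(K=3))
        fused = fuse_networks([a, a], SNFParams(K=3)).fused
        iu = np.triu_indices(10, 1)
        rho = stats.spearmanr(a.P[iu], fused[iu]).statistic
        assert rho > 0.8

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        vals1 = rng.normal(size=(25, 10))
        vals2 = rng.normal(size=(25, 10))
        params = SNFParams(K=3, T=5)
        perm = rng.permutation(10)
        samples = [f"s{i}" for i in range(10)]
        f1 = fuse_networks(
            [build_affinity(make_matrix(v, samples=samples), params) for v in (vals1, vals2)], params
        ).fused
        psamples = [samples[i] for i in perm]
        f2 = fuse_networks(
            [build_affinity(make_matrix(v[:, perm], samples=psamples), params) for v in (vals1, vals2)], params
        ).fused
        assert np.allclose(f1[np.ix_(perm, perm)], f2, atol=1e-9)

    def test_single_layer_passthrough(self):
        rng = np.random.default_rng(6)
        a = build_affinity(make_matrix(rng.normal(size=(15, 6))), SNFParams(K=2))
        fused = fuse_networks([a], SNFParams(K=2)).fused
        assert np.allclose(fused, (a.P + a.P.T) / 2, atol=1e-12)

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(7)
        a = build_affinity(make_matrix(rng.normal(size=(10, 5)), samples=list("abcde")), SNFParams(K=2))
        b = build_affinity(make_matrix(rng.normal(size=(10, 5)), samples=list("fghij")), SNFParams(K=2))
        with pytest.raises(ValueError, match="sample"):
            fuse_networks([a, b], SNFParams(K=2))

    def test_fused_symmetric_nonnegative(self, default_cohort):
        params = SNFParams()
        affs = [build_affinity(default_cohort.layers[l], params) for l in ("mrna", "protein")]
        fused = fuse_networks(affs, params).fused
        assert np.allclose(fused, fused.T, atol=1e-9)
        assert fused.min() >= 0


class TestSpectralCluster:
    def test_exact_two_blocks(self):
        W = _block_similarity()
        for seed in (0, 1, 99):
            labels = spectral_cluster(W, 2, seed=seed)
            assert (labels[:4] == labels[0]).all() and (labels[4:] == labels[4]).all()
            assert labels[0] != labels[4]

    def test_k_equals_n(self):
        W = _block_similarity(6)
        assert list(spectral_cluster(W, 6, seed=0)) == list(range(6))

    def test_canonical_label_order(self):
        labels = spectral_cluster(_block_similarity(), 2, seed=0)
        assert labels[0] == 0  # first sample always in cluster 0


class TestEstimateNumClusters:
    def test_three_blocks(self):
        W = np.full((9, 9), 0.05)
        for i in range(3):
            W[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = 0.9
        np.fill_diagonal(W, 1.0)
        best, gaps = estimate_num_clusters(W, k_max=5)
        assert best == 3

    def test_no_structure_ties_to_smallest_k(self):
        best, gaps = estimate_num_clusters(np.eye(10), k_max=5)
        assert best == 2
        assert np.allclose(gaps, gaps[0])


class TestExportNetwork:
    def test_dominant_pair_coverage(self):
        W = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.3], [0.2, 0.3, 1.0]])
        edges = export_network(W, ["a", "b", "c"])
        assert len(edges) >= 2
        assert set(edges["source"]).union(edges["target"]) == {"a", "b", "c"}
        assert (edges.iloc[0][["source", "target"]] == ["a", "b"]).all()

    def test_star_yields_n_minus_one_edges(self):
        n = 6
        W = np.full((n, n), 0.1)
        W[0, :] = W[:, 0] = 0.9
        np.fill_diagonal(W, 1.0)
        edges = export_network(W, [f"s{i}" for i in range(n)])
        assert len(edges) == n - 1

    def test_round_trip_weights_exact(self, tmp_path):
        rng = np.random.default_rng(8)
        W = rng.uniform(size=(5, 5))
        W = (W + W.T) / 2
        ids = [f"s{i}" for i in range(5)]
        export_network(W, ids, tmp_path / "edges.tsv")
        back = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        for _, row in back.iterrows():
            i, j = ids.index(row["source"]), ids.index(row["target"])
            assert row["weight"] == W[i, j]
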