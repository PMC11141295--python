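"""Clustering, evaluation metrics and denoising outputs."""

import numpy as np
import pytest

from stmda.downstream import (
    ari,
    cluster_embedding,
    davies_bouldin_spatial,
    domain_log_fold_change,
    filter_degs,
    morans_i,
    purity,
    silhouette_spatial,
)
from stmda.exceptions import ParameterError, ShapeError, StmdaError


def ari_bruteforce(a, b):
    """From-scratch pair-counting ARI via the contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    table = np.array([[(np.sum((a == x) & (b == y))) for y in ub] for x in ua])
    comb2 = lambda v: v * (v - 1) / 2
    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(len(a))
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_index - expected)


class TestClusterEmbedding:
    def test_two_separated_blobs_recovered(self, rng):
        H = np.concatenate(
            [rng.normal(0, 0.1, (5, 30)), rng.normal(5, 0.1, (5, 30))], axis=1
        )
        truth = np.repeat([0, 1], 30)
        result = cluster_embedding(H, target_domains=2, seed=0)
        assert result.n_domains == 2
        assert ari(result.labels, truth) == pytest.approx(1.0)

    def test_identical_columns_single_cluster(self):
        H = np.ones((4, 5))
        result = cluster_embedding(H, resolution=0.1, seed=0)
        assert result.n_domains == 1

    def test_same_seed_same_labels(self, rng):
        H = rng.standard_normal((6, 40))
        a = cluster_embedding(H, resolution=1.0, seed=2)
        b = cluster_embedding(H, resolution=1.0, seed=2)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_requires_exactly_one_mode(self, rng):
        H = rng.standard_normal((3, 10))
        with pytest.raises(ParameterError):
            cluster_embedding(H)
        with pytest.raises(ParameterError):
            cluster_embedding(H, target_domains=2, resolution=1.0)


class TestARI:
    def test_identical_labelings(self):
        assert ari([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_relabel_invariance(self):
        assert ari([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_matches_contingency_oracle(self, rng):
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 4, 30)
        assert ari(a, b) == pytest.approx(ari_bruteforce(a, b), abs=1e-12)

    def test_crossed_labels_against_oracle(self):
        a, b = [0, 0, 1, 1], [0, 1, 0, 1]
        assert ari(a, b) == pytest.approx(ari_bruteforce(a, b), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            ari([0, 1], [0, 1, 2])


class TestPurity:
    def test_perfect_agreement(self):
        assert purity([0, 1, 2, 0], [5, 6, 7, 5]) == pytest.approx(1.0)

    def test_mixed_cluster_direct_count(self):
        # single cluster holding classes of sizes 3 and 1
        assert purity([0, 0, 0, 0], [1, 1, 1, 2]) == pytest.approx(0.75)

    def test_matches_bruteforce_overlap(self, rng):
        labels = rng.integers(0, 3, 40)
        ref = rng.integers(0, 3, 40)
        total = sum(
            max(np.sum((labels == c) & (ref == r)) for r in np.unique(ref))
            for c in np.unique(labels)
        )
        assert purity(labels, ref) == pytest.approx(total / 40)

    def test_invariant_to_candidate_relabeling(self, rng):
        labels = rng.integers(0, 3, 30)
        ref = rng.integers(0, 3, 30)
        relabeled = (labels + 7) % 11
        assert purity(labels, ref) == pytest.approx(purity(relabeled, ref))


def silhouette_bruteforce(labels, coords):
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    n = len(labels)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    vals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            vals.append(0.0)
            continue
        a = d[i, same].mean()
        b = min(
            d[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestSpatialSilhouette:
    def test_disjoint_blobs_near_one(self, rng):
        coords = np.concatenate(
            [rng.normal(0, 0.05, (20, 2)), rng.normal(10, 0.05, (20, 2))]
        )
        labels = np.repeat([0, 1], 20)
        assert silhouette_spatial(labels, coords) > 0.8

    def test_random_labels_near_zero(self, rng):
        coords = rng.normal(0, 1.0, (60, 2))
        labels = rng.integers(0, 2, 60)
        assert abs(silhouette_spatial(labels, coords)) < 0.2

    def test_matches_bruteforce_on_small_fixture(self, rng):
        coords = rng.random((12, 2))
        labels = rng.integers(0, 3, 12)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 3, 12)
        assert silhouette_spatial(labels, coords) == pytest.approx(
            silhouette_bruteforce(labels, coords), abs=1e-10
        )

    def test_single_cluster_raises(self):
        with pytest.raises(StmdaError):
            silhouette_spatial(np.zeros(5, dtype=int), np.random.rand(5, 2))


def davies_bouldin_bruteforce(labels, coords):
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    clusters = np.unique(labels)
    centroids = np.array([coords[labels == c].mean(axis=0) for c in clusters])
    scatter = np.array(
        [
            np.mean(np.linalg.norm(coords[labels == c] - centroids[i], axis=1))
            for i, c in enumerate(clusters)
        ]
    )
    k = len(clusters)
    total = 0.0
    for i in range(k):
        worst = max(
            (scatter[i] + scatter[j])
            / np.linalg.norm(centroids[i] - centroids[j])
            for j in range(k)
            if j != i
        )
        total += worst
    return total / k


class TestDaviesBouldin:
    def test_point_mass_clusters_approach_zero(self):
        coords = np.array([[0.0, 0]] * 5 + [[100.0, 0]] * 5)
        labels = np.repeat([0, 1], 5)
        assert davies_bouldin_spatial(labels, coords) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula(self, rng):
        coords = rng.random((12, 2))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        assert davies_bouldin_spatial(labels, coords) == pytest.approx(
            davies_bouldin_bruteforce(labels, coords), abs=1e-10
        )

    def test_scale_invariance(self, rng):
        coords = rng.random((20, 2))
        labels = rng.integers(0, 3, 20)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 3, 20)
        a = davies_bouldin_spatial(labels, coords)
        b = davies_bouldin_spatial(labels, coords * 10.0)
        assert a == pytest.approx(b, rel=1e-10)


def morans_loops(values, coords, k):
    from stmda.graph import spatial_knn

    values = np.asarray(values, dtype=float)
    n = values.size
    z = values - values.mean()
    nb = spatial_knn(np.asarray(coords, dtype=float), k)
    w = np.zeros((n, n))
    for i in range(n):
        for j in nb[i]:
            w[i, j] = 1.0
    num = sum(
        w[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
    )
    return (n / w.sum()) * num / np.sum(z**2)


class TestMoransI:
    def test_smooth_gradient_on_chain(self):
        coords = np.column_stack([np.arange(20.0), np.zeros(20)])
        values = coords[:, 0]
        assert morans_i(values, coords, k=1) > 0.9

    def test_checkerboard_on_chain(self):
        coords = np.column_stack([np.arange(20.0), np.zeros(20)])
        values = np.resize([1.0, -1.0], 20)
        assert morans_i(values, coords, k=1) <= -0.9

    def test_matches_scalar_loop_formula(self, rng):
        coords = rng.random((8, 2))
        values = rng.standard_normal(8)
        assert morans_i(values, coords, k=3) == pytest.approx(
            morans_loops(values, coords, 3), abs=1e-12
        )

    def test_constant_vector_raises(self):
        with pytest.raises(StmdaError):
            morans_i(np.ones(5), np.random.rand(5, 2), k=2)


class TestLogFoldChange:
    def test_domain_exclusive_gene_is_large_positive(self):
        expr = np.array([[10.0, 10.0, 0.0, 0.0]])
        labels = np.array([0, 0, 1, 1])
        assert domain_log_fold_change(expr, labels, 0)[0] > 20

    def test_equal_means_give_zero(self):
        expr = np.array([[3.0, 3.0, 3.0, 3.0]])
        labels = np.array([0, 0, 1, 1])
        assert domain_log_fold_change(expr, labels, 0)[0] == pytest.approx(0.0)

    def test_hand_arithmetic_two_genes(self):
        expr = np.array([[4.0, 2.0, 1.0, 1.0], [1.0, 1.0, 2.0, 6.0]])
        labels = np.array([0, 0, 1, 1])
        lfc = domain_log_fold_change(expr, labels, 0)
        assert lfc[0] == pytest.approx(np.log2(3.0 / 1.0), abs=1e-6)
        assert lfc[1] == pytest.approx(np.log2(1.0 / 4.0), abs=1e-6)

    def test_deg_filter_threshold(self):
        expr = np.array([[9.0, 9.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]])
        labels = np.array([0, 0, 1, 1])
        assert filter_degs(expr, labels, 0, threshold=1.0).tolist() == [0]

    def test_empty_out_group_raises(self):
        with pytest.raises(ParameterError):
            domain_log_fold_change(np.ones((2, 3)), np.zeros(3, dtype=int), 0)
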