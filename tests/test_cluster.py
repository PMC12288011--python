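"""Hierarchical clustering, quality metrics and automatic thresholding."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from solvclust.cluster import (
    LINKAGE_METHODS,
    auto_threshold,
    cut,
    linkage,
    scores,
    silhouette,
)
from solvclust.pairdist import CondensedRMSDMatrix

from conftest import naive_single_linkage, pearson_loop


def cm(condensed):
    condensed = np.asarray(condensed, float)
    M = int((1 + np.sqrt(1 + 8 * len(condensed))) / 2)
    return CondensedRMSDMatrix(condensed, M)


def two_block_matrix(n1=5, n2=5, intra=1.0, inter=10.0):
    M = n1 + n2
    sq = np.full((M, M), inter)
    sq[:n1, :n1] = intra
    sq[n1:, n1:] = intra
    np.fill_diagonal(sq, 0.0)
    return CondensedRMSDMatrix(squareform(sq), M)


class TestLinkage:
    def test_forced_merge_order_single(self):
        tree = linkage(cm([1.0, 5.0, 5.0]), "single")
        np.testing.assert_allclose(tree[:, 2], [1.0, 5.0])

    def test_equal_distances_single_equals_complete(self):
        m = cm([2.0] * 6)  # 4 points, all pairwise distances equal
        ts = linkage(m, "single")
        tc = linkage(m, "complete")
        np.testing.assert_allclose(ts[:, 2], tc[:, 2])

    def test_unknown_method_lists_choices(self):
        with pytest.raises(ValueError) as err:
            linkage(cm([1.0, 2.0, 3.0]), "bogus")
        for name in LINKAGE_METHODS:
            assert name in str(err.value)

    def test_single_linkage_matches_naive_oracle(self, rng):
        sq = squareform(rng.uniform(0.5, 5.0, size=28))  # 8 points
        m = CondensedRMSDMatrix(squareform(sq), 8)
        tree = linkage(m, "single")
        oracle_heights = naive_single_linkage(sq)
        np.testing.assert_allclose(np.sort(tree[:, 2]), np.sort(oracle_heights))

    def test_heights_monotone_for_single_and_ward(self, rng):
        for method in ("single", "ward"):
            m = CondensedRMSDMatrix(rng.uniform(0.5, 5.0, size=45), 10)
            tree = linkage(m, method)
            assert np.all(np.diff(tree[:, 2]) >= -1e-12)


class TestCut:
    def test_above_root_single_cluster(self):
        tree = linkage(cm([1.0, 5.0, 5.0]), "single")
        res = cut(tree, 100.0)
        assert res.n_clusters == 1

    def test_below_first_merge_all_singletons(self):
        tree = linkage(cm([1.0, 5.0, 5.0]), "single")
        assert cut(tree, 0.5).n_clusters == 3

    def test_forced_two_clusters(self):
        tree = linkage(cm([1.0, 5.0, 5.0]), "single")
        res = cut(tree, 2.0)
        assert res.n_clusters == 2
        assert res.labels[0] == res.labels[1] != res.labels[2]

    def test_labels_numbered_by_first_appearance(self):
        sq = np.array([
            [0, 9, 1, 9],
            [9, 0, 9, 1],
            [1, 9, 0, 9],
            [9, 1, 9, 0.0],
        ])
        tree = linkage(cm(squareform(sq)), "single")
        res = cut(tree, 2.0)
        # frame 1 always opens cluster 1, frame 2 opens cluster 2
        np.testing.assert_array_equal(res.labels, [1, 2, 1, 2])

    def test_monotone_in_threshold(self, rng):
        m = CondensedRMSDMatrix(rng.uniform(0.5, 5.0, size=45), 10)
        tree = linkage(m, "average")
        counts = [cut(tree, t).n_clusters for t in np.linspace(0.1, 6.0, 40)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_rejects_nonpositive_threshold(self):
        tree = linkage(cm([1.0, 5.0, 5.0]), "single")
        with pytest.raises(ValueError):
            cut(tree, 0.0)


class TestSilhouette:
    def test_two_tight_separated_groups(self):
        m = two_block_matrix(intra=0.1, inter=10.0)
        labels = np.array([1] * 5 + [2] * 5)
        assert silhouette(m, labels) > 0.9

    def test_all_equal_distances_score_zero(self):
        m = cm([1.0] * 6)  # 4 points: a(i) == b(i) == 1
        labels = np.array([1, 1, 2, 2])
        assert silhouette(m, labels) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_four_point_example(self):
        # intra=1, inter=10: s(i) = 1 - 1/10 = 0.9 for every point
        m = two_block_matrix(2, 2, intra=1.0, inter=10.0)
        labels = np.array([1, 1, 2, 2])
        assert silhouette(m, labels) == pytest.approx(0.9)

    def test_single_cluster_undefined(self):
        m = cm([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            silhouette(m, np.array([1, 1, 1]))


class TestScores:
    def test_cpcc_is_one_on_ultrametric_input(self):
        # a matrix that is exactly tree-consistent: cophenetic == original
        m = two_block_matrix(3, 3, intra=1.0, inter=8.0)
        tree = linkage(m, "average")
        sc = scores(m, cut(tree, 4.0).labels, tree)
        assert sc["cpcc"] == pytest.approx(1.0, abs=1e-10)

    def test_cpcc_matches_explicit_pearson_loop(self, rng):
        m = CondensedRMSDMatrix(rng.uniform(0.5, 5.0, size=45), 10)
        tree = linkage(m, "average")
        sc = scores(m, cut(tree, np.median(tree[:, 2])).labels, tree)
        import scipy.cluster.hierarchy as sch

        coph = sch.cophenet(tree)
        assert sc["cpcc"] == pytest.approx(pearson_loop(m.d, coph))

    def test_degenerate_coincident_clusters_error(self):
        m = cm([0.0] * 6)  # 4 coincident frames
        tree = linkage(m, "single")
        labels = np.array([1, 1, 2, 2])
        with pytest.raises(ValueError):
            scores(m, labels, tree)

    def test_all_four_scores_present(self, rng):
        m = two_block_matrix()
        tree = linkage(m, "average")
        sc = scores(m, cut(tree, 5.0).labels, tree)
        assert set(sc) == {"ss", "ch", "db", "cpcc"}


class TestAutoThreshold:
    def test_two_block_matrix_finds_two_clusters(self):
        m = two_block_matrix(intra=0.5, inter=10.0)
        tree = linkage(m, "average")
        thr, res = auto_threshold(m, tree)
        assert res.n_clusters == 2
        assert 0.5 < thr < 10.0

    def test_maximizes_over_exhaustive_scan(self, rng):
        m = CondensedRMSDMatrix(rng.uniform(0.5, 5.0, size=45), 10)
        tree = linkage(m, "average")
        thr, res = auto_threshold(m, tree)
        chosen_ss = silhouette(m, res.labels)
        # every distinct merge height is a candidate cut
        for h in np.unique(tree[:, 2]):
            for t in (h - 1e-9, h + 1e-9):
                if t <= 0:
                    continue
                other = cut(tree, t)
                if 2 <= other.n_clusters <= m.M - 1:
                    assert silhouette(m, other.labels) <= chosen_ss + 1e-12

    def test_tie_returns_smallest_threshold(self):
        # 3 equidistant points: every 2-cluster cut has the same SS
        m = cm([4.0, 4.0, 4.0])
        tree = linkage(m, "single")
        thr, res = auto_threshold(m, tree)
        assert res.n_clusters == 2
        # smallest candidate producing 2 clusters is just below height 4
        assert thr < 4.0

    def test_needs_three_frames(self):
        m = cm([1.0])
        tree = linkage(m, "single")
        with pytest.raises(ValueError):
            auto_threshold(m, tree)
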