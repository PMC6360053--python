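import numpy as np
import pytest

from conftest import brute_force_cjc, brute_force_neighborhood, random_bipartite
from nbmda.augment import (
    build_network_triple,
    cjc,
    cjc_matrix,
    knn_augment_by_disease,
    knn_augment_by_mirna,
    knn_neighbors,
    pair_neighborhood,
    rank_for_disease,
    score_all,
)
from nbmda.io_formats import AssociationMatrix


class TestKnnAugmentation:
    def test_unanimous_neighbors_add_edge(self):
        # diseases 1..3 all carry miRNA 0; disease 0 similar to all three
        A = np.array([[0, 1], [1, 0], [1, 0], [1, 0]], dtype=np.int8)
        Sd = np.full((4, 4), 0.9)
        np.fill_diagonal(Sd, 1.0)
        sda = knn_augment_by_disease(A, Sd, k=3, vote_threshold=2)
        assert sda[0, 0] == 1

    def test_single_vote_below_majority(self):
        A = np.array([[0, 0], [1, 0], [0, 1], [0, 1]], dtype=np.int8)
        Sd = np.full((4, 4), 0.9)
        np.fill_diagonal(Sd, 1.0)
        sda = knn_augment_by_disease(A, Sd, k=3, vote_threshold=2)
        assert sda[0, 0] == 0  # only disease 1 votes for miRNA 0
        assert sda[0, 1] == 1  # diseases 2 and 3 vote for miRNA 1

    def test_augmentation_only_adds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = random_bipartite(rng, 8, 8, 0.3)
            S = rng.random((8, 8))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 1.0)
            sda = knn_augment_by_disease(A, S, k=3)
            assert np.all(sda >= A)

    def test_raising_vote_threshold_shrinks_edges(self):
        rng = np.random.default_rng(1)
        A = random_bipartite(rng, 10, 10, 0.3)
        S = rng.random((10, 10))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        prev = None
        for vt in (1, 2, 3):
            cur = knn_augment_by_disease(A, S, k=3, vote_threshold=vt)
            if prev is not None:
                assert np.all(cur <= prev)
            prev = cur

    def test_mirna_side_is_transpose_dual(self):
        rng = np.random.default_rng(2)
        A = random_bipartite(rng, 7, 9, 0.3)
        Sm = rng.random((9, 9))
        Sm = (Sm + Sm.T) / 2
        np.fill_diagonal(Sm, 1.0)
        sma = knn_augment_by_mirna(A, Sm, k=3, vote_threshold=2)
        dual = knn_augment_by_disease(A.T, Sm, k=3, vote_threshold=2).T
        np.testing.assert_array_equal(sma, dual)

    def test_all_zero_matrix_stays_zero(self):
        S = np.eye(5)
        assert knn_augment_by_mirna(np.zeros((4, 5), np.int8), S, k=3).sum() == 0

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError, match="smaller"):
            knn_augment_by_disease(np.zeros((3, 2), np.int8), np.eye(3), k=3)

    def test_neighbor_ties_break_by_index_and_exclude_self(self):
        nbrs = knn_neighbors(np.eye(4), k=2)
        np.testing.assert_array_equal(nbrs[0], [1, 2])
        np.testing.assert_array_equal(nbrs[3], [0, 1])
        assert all(i not in nbrs[i] for i in range(4))


class TestPairNeighborhood:
    def test_three_edge_toy(self, toy_assoc):
        nb = pair_neighborhood(toy_assoc.matrix, 0, 0)
        assert nb.cn_mirnas == {1} and nb.cn_diseases == {1}
        assert nb.cn_count == 2 and nb.lcl_count == 1 and nb.degree_sum == 2

    def test_isolated_seed_all_zero(self):
        X = np.zeros((3, 3), np.int8)
        X[1, 1] = 1
        nb = pair_neighborhood(X, 0, 0)
        assert nb.cn_count == nb.lcl_count == nb.degree_sum == 0

    def test_existing_seed_edge_removed_first(self, toy_assoc):
        X = toy_assoc.matrix.copy()
        X[0, 0] = 1  # add the seed edge; removal must restore the toy counts
        nb = pair_neighborhood(X, 0, 0)
        assert nb.cn_count == 2 and nb.lcl_count == 1 and nb.degree_sum == 2

    def test_cn_count_consistency(self):
        rng = np.random.default_rng(3)
        X = random_bipartite(rng, 6, 6, 0.4)
        nb = pair_neighborhood(X, 2, 3)
        assert nb.cn_count == len(nb.cn_mirnas) + len(nb.cn_diseases)
        assert nb.lcl_count <= len(nb.cn_mirnas) * len(nb.cn_diseases)


class TestCjcOracle:
    def test_three_edge_toy_value(self, toy_assoc):
        assert cjc(toy_assoc.matrix, 0, 0) == pytest.approx(1.0)

    def test_no_quadrangle_zero(self):
        X = np.zeros((3, 3), np.int8)
        X[0, 1] = 1
        assert cjc(X, 0, 0) == 0.0

    def test_complete_bipartite_matches_brute_force(self):
        X = np.ones((2, 2), np.int8)
        for i in range(2):
            for j in range(2):
                assert cjc(X, i, j) == pytest.approx(brute_force_cjc(X, i, j), abs=1e-12)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_d, n_m = rng.integers(2, 11, size=2)
            X = random_bipartite(rng, n_d, n_m, rng.uniform(0.1, 0.6))
            i, j = rng.integers(0, n_d), rng.integers(0, n_m)
            cn_m, cn_d, lcl, deg = brute_force_neighborhood(X, i, j)
            nb = pair_neighborhood(X, i, j)
            assert set(nb.cn_mirnas) == cn_m and set(nb.cn_diseases) == cn_d
            assert nb.lcl_count == lcl and nb.degree_sum == deg
            assert cjc(X, i, j) == pytest.approx(brute_force_cjc(X, i, j), abs=1e-12)

    def test_degree_sum_equals_neighbor_set_union(self):
        # in a bipartite graph the two neighbor sets are disjoint, so the
        # denominator |N(d) U N(m)| is exactly deg(d) + deg(m)
        rng = np.random.default_rng(8)
        X = random_bipartite(rng, 8, 8, 0.4)
        i, j = 2, 5
        Xp = X.copy()
        Xp[i, j] = 0
        union = {("m", k) for k in np.flatnonzero(Xp[i])} | {
            ("d", l) for l in np.flatnonzero(Xp[:, j])
        }
        assert pair_neighborhood(X, i, j).degree_sum == len(union)

    def test_cjc_matrix_matches_per_pair(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            X = random_bipartite(rng, 7, 8, rng.uniform(0.1, 0.6))
            M = cjc_matrix(X)
            for i in range(7):
                for j in range(8):
                    assert M[i, j] == pytest.approx(cjc(X, i, j), abs=1e-12)


class TestScoreAll:
    def _triple(self, A, Sd=None, Sm=None, k=2):
        n_d, n_m = A.shape
        Sd = Sd if Sd is not None else np.eye(n_d)
        Sm = Sm if Sm is not None else np.eye(n_m)
        return build_network_triple(A, Sd, Sm, k=k, vote_threshold=1)

    def test_identical_networks_reduce_to_single_cjc(self):
        # when augmentation adds nothing the geometric mean collapses to
        # the plain single-network index
        from nbmda.augment import NetworkTriple

        rng = np.random.default_rng(10)
        A = random_bipartite(rng, 6, 6, 0.4)
        triple = NetworkTriple(A, A.copy(), A.copy(), k=3, vote_threshold=2)
        np.testing.assert_allclose(score_all(triple).scores, cjc_matrix(A), atol=1e-12)

    def test_zero_annihilates(self):
        A = np.zeros((3, 3), np.int8)
        A[0, 0] = 1
        A[1, 1] = 1
        triple = self._triple(A)
        assert np.all(score_all(triple).scores == 0)

    def test_geometric_mean_of_ones(self, toy_assoc):
        A = toy_assoc.matrix
        triple = self._triple(A, k=1)
        s = score_all(triple, diagnostics=True)
        i, j = 0, 0
        expect = np.cbrt(
            s.per_network_cjc["mda"][i, j]
            * s.per_network_cjc["sda"][i, j]
            * s.per_network_cjc["sma"][i, j]
        )
        assert s.scores[i, j] == pytest.approx(expect, abs=1e-12)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        A = random_bipartite(rng, 6, 5, 0.4)
        Sd = rng.random((6, 6))
        Sd = (Sd + Sd.T) / 2
        np.fill_diagonal(Sd, 1.0)
        Sm = rng.random((5, 5))
        Sm = (Sm + Sm.T) / 2
        np.fill_diagonal(Sm, 1.0)
        perm = rng.permutation(6)
        s1 = score_all(build_network_triple(A, Sd, Sm, 2, 1)).scores
        s2 = score_all(
            build_network_triple(A[perm], Sd[np.ix_(perm, perm)], Sm, 2, 1)
        ).scores
        np.testing.assert_allclose(s2, s1[perm], atol=1e-12)


class TestRankForDisease:
    def _scored(self):
        A = AssociationMatrix(
            np.array([[1, 0, 0, 0], [0, 0, 0, 0]], np.int8), ["d1", "d2"], list("abcd")
        )
        scores = np.array([[0.9, 0.2, 0.8, 0.2], [0.0, 0.0, 0.0, 0.0]])
        return A, scores

    def test_known_pairs_excluded_and_sorted(self):
        A, scores = self._scored()
        preds = rank_for_disease(scores, A, "d1", top_n=50)
        assert [m for m, _ in preds.rows] == ["c", "b", "d"]

    def test_tie_break_by_index(self):
        A, scores = self._scored()
        preds = rank_for_disease(scores, A, "d2", top_n=2)
        assert [m for m, _ in preds.rows] == ["a", "b"]

    def test_unknown_disease_errors(self):
        A, scores = self._scored()
        with pytest.raises(KeyError):
            rank_for_disease(scores, A, "dX")
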