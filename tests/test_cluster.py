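"""Bray-Curtis / UPGMA clustering, k selection, PERMANOVA, and PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from plantdemog.cluster import (
    bray_curtis,
    cut_dendrogram,
    dendrogram_to_newick,
    pairwise_permanova,
    pca,
    permanova,
    select_k,
    upgma,
)


def upgma_by_hand(D, labels):
    """Tiny independent UPGMA: literal greedy merging with size-weighted
    average distances.  Returns the merge heights in order."""
    clusters = {i: [i] for i in range(len(labels))}
    dist = {frozenset((a, b)): D[a][b] for a in clusters for b in clusters if a < b}
    heights = []
    next_id = len(labels)
    while len(clusters) > 1:
        pair = min(dist, key=lambda k: dist[k])
        a, b = sorted(pair)
        h = dist[pair]
        heights.append(h)
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        new_dist = {}
        for key in list(dist):
            if a in key or b in key:
                del dist[key]
        for c, members in clusters.items():
            d = np.mean([D[x][y] for x in merged for y in members])
            new_dist[frozenset((next_id, c))] = d
        clusters[next_id] = merged
        dist.update(new_dist)
        next_id += 1
    return heights


class TestBrayCurtis:
    def test_hand_example(self):
        D = bray_curtis(np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]]))
        assert D[0, 1] == pytest.approx(0.5)

    def test_identical_rows(self):
        D = bray_curtis(np.array([[0.3, 0.7], [0.3, 0.7]]))
        assert D[0, 1] == 0.0

    def test_disjoint_supports(self):
        D = bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert D[0, 1] == pytest.approx(1.0)

    def test_all_zero_rows_are_identical(self):
        D = bray_curtis(np.zeros((2, 3)))
        assert D[0, 1] == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            bray_curtis(np.array([[1.0, -0.1], [0.0, 1.0]]))

    def test_bounds_and_symmetry(self, archetype_bundle):
        from plantdemog.lifetable import TRAIT_COLUMNS, normalize_trait_table, trait_table

        records, _ = archetype_bundle
        X = normalize_trait_table(trait_table(records))[TRAIT_COLUMNS]
        D = bray_curtis(X)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert (D >= 0).all() and (D <= 1).all()


class TestUpgma:
    def test_two_leaves(self):
        dend = upgma(np.array([[0.0, 0.4], [0.4, 0.0]]), ["A", "B"])
        assert dend.merges[0, 2] == pytest.approx(0.4)

    def test_three_leaf_hand_merge(self):
        D = np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.6], [0.4, 0.6, 0.0]])
        dend = upgma(D, ["A", "B", "C"])
        np.testing.assert_allclose(dend.merges[:, 2], [0.1, 0.5])

    def test_matches_hand_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            m = int(rng.integers(3, 7))
            X = rng.random((m, 4))
            D = bray_curtis(X)
            dend = upgma(D)
            np.testing.assert_allclose(
                dend.merges[:, 2],
                upgma_by_hand(D.tolist(), list(range(m))),
                atol=1e-12,
            )

    def test_monotone_heights(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = int(rng.integers(3, 12))
            D = bray_curtis(rng.random((m, 5)))
            dend = upgma(D)
            heights = dend.merges[:, 2]
            assert (np.diff(heights) >= -1e-12).all()

    def test_ultrametric_input_reproduced_cophenetically(self):
        # distances from a perfectly ultrametric 4-leaf tree
        D = np.array(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ]
        )
        dend = upgma(D)
        np.testing.assert_allclose(dend.cophenetic(), D, atol=1e-12)

    def test_newick_export_parses_with_correct_depths(self):
        import dendropy

        D = np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.6], [0.4, 0.6, 0.0]])
        dend = upgma(D, ["A", "B", "C"])
        tree = dendropy.Tree.get(data=dendrogram_to_newick(dend), schema="newick")
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        depths = {l.taxon.label: l.root_distance for l in tree.leaf_node_iter()}
        assert depths["A"] == pytest.approx(0.5)
        assert depths["C"] == pytest.approx(0.5)


class TestCut:
    @pytest.fixture
    def three_leaf(self):
        D = np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.6], [0.4, 0.6, 0.0]])
        return upgma(D, ["A", "B", "C"])

    def test_default_cut_splits_far_leaf(self, three_leaf):
        labels = cut_dendrogram(three_leaf, 0.3)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_cut_at_zero_gives_singletons(self, three_leaf):
        assert cut_dendrogram(three_leaf, 0.0).nunique() == 3

    def test_cut_above_max_gives_one_cluster(self, three_leaf):
        assert cut_dendrogram(three_leaf, 1.0).nunique() == 1

    def test_labels_are_dense_from_one(self, three_leaf):
        labels = cut_dendrogram(three_leaf, 0.3)
        assert set(labels) == set(range(1, labels.nunique() + 1))


class TestSelectK:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.01, (20, 2)), rng.normal(1, 0.01, (20, 2))]
        )
        k, profile = select_k(X, range(1, 8), seed=0)
        assert k == 2
        assert (np.diff(profile["wss"]) <= 1e-9).all()

    def test_identical_points(self):
        k, _ = select_k(np.ones((10, 3)), range(1, 5), seed=0)
        assert k == 1

    def test_three_archetype_clouds(self, archetype_bundle):
        from plantdemog.lifetable import TRAIT_COLUMNS, normalize_trait_table, trait_table

        records, _ = archetype_bundle
        X = normalize_trait_table(trait_table(records))[TRAIT_COLUMNS]
        k, _ = select_k(X.to_numpy(), range(1, 8), seed=0)
        assert k == 3


def brute_force_pseudo_f(D, labels):
    """Literal evaluation of the PERMANOVA definition."""
    m = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(D[a][b] ** 2 for a in range(m) for b in range(a + 1, m)) / m
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(m) if labels[i] == g]
        ss_within += sum(
            D[a][b] ** 2 for a in idx for b in idx if a < b
        ) / len(idx)
    g = len(groups)
    return ((ss_total - ss_within) / (g - 1)) / (ss_within / (m - g))


class TestPermanova:
    def test_hand_matrix_matches_brute_force(self):
        rng = np.random.default_rng(5)
        X = rng.random((6, 3))
        D = bray_curtis(X)
        labels = np.array([0, 0, 0, 1, 1, 1])
        f, _ = permanova(D, labels, n_perm=99, seed=0)
        assert f == pytest.approx(brute_force_pseudo_f(D.tolist(), labels.tolist()))

    def test_exhaustive_permutation_p_value(self):
        # 4 points, 2+2 groups: compare against full enumeration
        rng = np.random.default_rng(8)
        D = bray_curtis(rng.random((4, 3)))
        labels = np.array([0, 0, 1, 1])
        f_obs, p = permanova(D, labels, n_perm=9999, seed=1)
        perms = [
            brute_force_pseudo_f(D.tolist(), list(perm))
            for perm in set(itertools.permutations(labels.tolist()))
        ]
        exact = sum(f >= f_obs - 1e-12 for f in perms) / len(perms)
        assert p == pytest.approx(exact, abs=0.05)

    def test_matches_skbio_oracle(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(11)
        X = rng.random((12, 4))
        X[:6] += 0.8
        D = bray_curtis(X)
        labels = np.array([0] * 6 + [1] * 6)
        f, _ = permanova(D, labels, n_perm=99, seed=0)
        res = skbio_permanova(DistanceMatrix(D), labels.astype(str), permutations=99)
        assert f == pytest.approx(res["test statistic"], rel=1e-9)

    def test_single_group_errors(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            permanova(D, np.zeros(3, dtype=int))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        D = bray_curtis(rng.random((8, 3)))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        f1, p1 = permanova(D, labels, n_perm=199, seed=4)
        f2, p2 = permanova(D, 1 - labels, n_perm=199, seed=4)
        assert f1 == pytest.approx(f2)
        assert p1 == pytest.approx(p2)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(17)
        D = bray_curtis(rng.random((9, 3)))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert permanova(D, labels, seed=7) == permanova(D, labels, seed=7)

    def test_singleton_group_yields_nan_p(self):
        rng = np.random.default_rng(19)
        D = bray_curtis(rng.random((5, 3)))
        labels = np.array([0, 0, 0, 0, 1])
        f, p = permanova(D, labels, n_perm=49, seed=0)
        assert np.isfinite(f) and np.isnan(p)

    def test_pairwise_table(self):
        rng = np.random.default_rng(23)
        X = rng.random((15, 4))
        X[:5] += 1.0
        D = bray_curtis(np.clip(X, 0, None))
        labels = np.array([0] * 5 + [1] * 5 + [2] * 5)
        table = pairwise_permanova(D, labels, n_perm=199, seed=0)
        assert len(table) == 3
        assert (table["p_holm"].dropna() >= table["p_raw"].dropna() - 1e-12).all()
        assert (table["p_holm"].dropna() <= 1.0).all()


class TestPCA:
    def test_duplicated_columns_give_single_component(self):
        rng = np.random.default_rng(1)
        col = rng.random(20)
        X = np.column_stack([col, col])
        _, _, varexp = pca(X)
        assert varexp[0] == pytest.approx(100.0)

    def test_symmetric_bivariate_loading(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(4000)
        e = rng.standard_normal(4000) * 0.02
        X = np.column_stack([z + e, z - e])
        loadings, _, _ = pca(X)
        np.testing.assert_allclose(
            np.abs(loadings[:, 0]), [1 / np.sqrt(2)] * 2, atol=0.01
        )
        assert loadings[np.argmax(np.abs(loadings[:, 0])), 0] > 0

    def test_variance_explained_properties(self, archetype_bundle):
        from plantdemog.lifetable import TRAIT_COLUMNS, normalize_trait_table, trait_table

        records, _ = archetype_bundle
        X = normalize_trait_table(trait_table(records))[TRAIT_COLUMNS]
        loadings, scores, varexp = pca(X)
        assert varexp.sum() == pytest.approx(100.0)
        assert (varexp >= -1e-9).all()
        assert (np.diff(varexp) <= 1e-9).all()
        np.testing.assert_allclose(
            loadings.to_numpy().T @ loadings.to_numpy(),
            np.eye(loadings.shape[1]),
            atol=1e-9,
        )
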