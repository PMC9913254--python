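"""Complete-linkage trees, tree descriptors and phenotype counting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

import lesionforest as lf
from lesionforest.patient_trees import (
    DEGENERACY_HEIGHT,
    build_patient_trees,
    mean_pairwise_distance,
    merge_height_total,
)
from lesionforest.synthetic_cohort import phenotype_depth_templates


def _tree_from_points(points):
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    D = lf.pairwise_distance_matrix(X)
    return lf.complete_linkage_tree(D, [f"L{i}" for i in range(len(X))]), X


class TestDistances:
    def test_identical_profiles_zero_matrix(self):
        D = lf.pairwise_distance_matrix(np.ones((3, 6)) * 0.4)
        assert D == pytest.approx(np.zeros((3, 3)))

    def test_unit_vector_distance(self):
        a = np.zeros(6) + 1e-6
        b = a.copy()
        b[0] += 1.0
        D = lf.pairwise_distance_matrix(np.vstack([a, b]))
        assert D[0, 1] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.uniform(0, 1, (12, 6))
        D = lf.pairwise_distance_matrix(X)
        for i in range(12):
            for j in range(12):
                assert D[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), abs=1e-12
                )


class TestCompleteLinkage:
    def test_toy_three_point_tree(self):
        tree, _ = _tree_from_points([0.0, 1.0, 5.0])
        assert [h for _, _, h in tree.merges] == pytest.approx([1.0, 5.0])
        # edges: two leaf edges of 1, leaf edge of 5, internal edge 5-1=4
        assert lf.sum_branch_lengths(tree) == pytest.approx(11.0)
        assert merge_height_total(tree) == pytest.approx(6.0)

    def test_two_leaves_single_merge(self):
        tree, _ = _tree_from_points([2.0, 7.0])
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == pytest.approx(5.0)

    def test_heights_match_scipy_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            X = rng.standard_normal((n, 4))
            tree, _ = _tree_from_points(X)
            ref = linkage(squareform(lf.pairwise_distance_matrix(X), checks=False),
                          method="complete")
            np.testing.assert_allclose(tree.heights, ref[:, 2], atol=1e-10)

    def test_heights_are_monotone(self, rng):
        for _ in range(30):
            X = rng.uniform(0, 1, (int(rng.integers(3, 10)), 6))
            tree, _ = _tree_from_points(X)
            assert (np.diff(tree.heights) >= -1e-12).all()

    def test_leaf_order_invariance_of_heights(self, rng):
        X = rng.uniform(0, 1, (7, 6))
        tree, _ = _tree_from_points(X)
        perm = rng.permutation(7)
        tree_p, _ = _tree_from_points(X[perm])
        np.testing.assert_allclose(tree.heights, tree_p.heights, atol=1e-12)

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            lf.complete_linkage_tree(D, ["a", "b", "c"])

    def test_tie_break_is_lexicographic(self):
        # four equidistant-ish points: 0-1 and 2-3 both at distance 1
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        tree, _ = _tree_from_points(X)
        first_members = {0, 1}
        a, b, h = tree.merges[0]
        assert {a, b} == first_members and h == pytest.approx(1.0)

    def test_newick_contains_all_leaves(self):
        tree, _ = _tree_from_points([0.0, 1.0, 5.0])
        nwk = tree.to_newick()
        assert nwk.endswith(");") and all(f"L{i}" in nwk for i in range(3))


class TestDescriptors:
    def test_identical_profiles_zero_descriptors(self):
        X = np.tile(np.linspace(0.1, 0.6, 6), (4, 1))
        tree, _ = _tree_from_points(X)
        assert lf.sum_branch_lengths(tree) == 0.0
        assert lf.dispersion(X) == 0.0

    def test_two_point_dispersion_closed_form(self, rng):
        a, b = rng.uniform(0, 1, (2, 6))
        d = np.linalg.norm(a - b)
        assert lf.dispersion(np.vstack([a, b])) == pytest.approx(d / 2)

    def test_dispersion_matches_brute_force(self, rng):
        X = rng.uniform(0, 1, (9, 6))
        c = X.mean(axis=0)
        brute = np.sqrt(np.mean([np.sum((x - c) ** 2) for x in X]))
        assert lf.dispersion(X) == pytest.approx(brute, abs=1e-12)

    def test_branch_length_scales_homogeneously(self, rng):
        X = rng.uniform(0, 1, (6, 6))
        t1, _ = _tree_from_points(X)
        t2, _ = _tree_from_points(3.0 * X)
        assert lf.sum_branch_lengths(t2) == pytest.approx(3 * lf.sum_branch_lengths(t1))

    def test_moving_a_lesion_outward_increases_both(self, rng):
        X = rng.uniform(0.3, 0.7, (5, 6))
        ray = X[0] - X.mean(axis=0)
        ray /= np.linalg.norm(ray)
        X2 = X.copy()
        X2[0] = X[0] + 0.5 * ray
        assert lf.dispersion(X2) > lf.dispersion(X)
        t1, _ = _tree_from_points(X)
        t2, _ = _tree_from_points(X2)
        assert lf.sum_branch_lengths(t2) > lf.sum_branch_lengths(t1)


class TestValidityIndices:
    def test_tight_separated_pairs_limits(self):
        X = np.array([[0.0, 0], [0.01, 0], [5.0, 5], [5.01, 5]])
        labels = np.array([0, 0, 1, 1])
        D = lf.pairwise_distance_matrix(X)
        assert lf.silhouette_index(D, labels) > 0.99
        assert lf.davies_bouldin_index(X, labels) < 0.01
        assert lf.calinski_harabasz_index(X, labels) > 1e4

    def test_random_labels_on_structureless_data(self, rng):
        X = rng.uniform(0, 1, (60, 6))
        labels = rng.integers(0, 2, 60)
        D = lf.pairwise_distance_matrix(X)
        assert abs(lf.silhouette_index(D, labels)) < 0.15

    def test_matches_textbook_oracle(self, rng):
        """Cross-check all three indices against naive textbook formulas."""
        X = rng.standard_normal((25, 4))
        labels = rng.integers(0, 3, 25)
        D = lf.pairwise_distance_matrix(X)

        # silhouette, naive
        sil = []
        for i in range(25):
            own = labels[i]
            a = D[i, (labels == own) & (np.arange(25) != i)].mean()
            b = min(D[i, labels == g].mean() for g in set(labels) - {own})
            sil.append((b - a) / max(a, b))
        assert lf.silhouette_index(D, labels) == pytest.approx(np.mean(sil), abs=1e-9)

        # Davies-Bouldin, naive
        cents = {g: X[labels == g].mean(axis=0) for g in set(labels)}
        s = {g: np.mean([np.linalg.norm(x - cents[g]) for x in X[labels == g]])
             for g in set(labels)}
        db = np.mean([
            max((s[g] + s[h]) / np.linalg.norm(cents[g] - cents[h])
                for h in set(labels) if h != g)
            for g in set(labels)
        ])
        assert lf.davies_bouldin_index(X, labels) == pytest.approx(db, abs=1e-9)

        # Calinski-Harabasz, naive
        grand = X.mean(axis=0)
        B = sum((labels == g).sum() * np.sum((cents[g] - grand) ** 2) for g in set(labels))
        W = sum(np.sum((X[labels == g] - cents[g]) ** 2) for g in set(labels))
        ch = (B / (len(set(labels)) - 1)) / (W / (25 - len(set(labels))))
        assert lf.calinski_harabasz_index(X, labels) == pytest.approx(ch, abs=1e-9)

    def test_degenerate_cluster_counts_rejected(self):
        X = np.random.default_rng(0).uniform(0, 1, (8, 3))
        with pytest.raises(ValueError):
            lf.silhouette_index(lf.pairwise_distance_matrix(X), np.zeros(8, dtype=int))
        with pytest.raises(ValueError):
            lf.davies_bouldin_index(X, np.arange(8))


class TestCountPhenotypes:
    def test_three_planted_groups_recovered_by_all_indices(self, rng):
        T = phenotype_depth_templates(3)
        frame, _, _ = lf.simulate_from_templates(T, [6, 5, 6], separation_ratio=10, seed=3)
        X = frame.to_numpy()
        tree, _ = _tree_from_points(X)
        for index in ("silhouette", "ch", "db"):
            assert lf.count_phenotypes(tree, X, index=index) == 3

    def test_near_degenerate_tree_warns(self):
        rng = np.random.default_rng(0)
        X = 0.5 + 1e-9 * rng.standard_normal((5, 6))
        tree, _ = _tree_from_points(X)
        assert tree.merges[-1][2] < DEGENERACY_HEIGHT
        with pytest.warns(UserWarning, match="degenerate"):
            lf.count_phenotypes(tree, X, index="silhouette")

    def test_two_identical_lesions_are_one_phenotype(self):
        X = np.tile(np.full(6, 0.5), (2, 1))
        tree, _ = _tree_from_points(X)
        assert lf.count_phenotypes(tree, X, two_lesion_threshold=0.0) == 1

    def test_two_lesion_threshold_decides(self):
        X = np.vstack([np.full(6, 0.2), np.full(6, 0.8)])
        tree, _ = _tree_from_points(X)
        assert lf.count_phenotypes(tree, X, two_lesion_threshold=0.1) == 2
        assert lf.count_phenotypes(tree, X, two_lesion_threshold=10.0) == 1


class TestDescriptorTable:
    def test_one_row_per_patient(self, default_profiles):
        table = lf.tree_descriptor_table(default_profiles)
        assert len(table) == 55
        assert (table["n_lesions"] >= 2).all()
        for col in ("n_phenotypes_silhouette", "n_phenotypes_ch", "n_phenotypes_db"):
            assert ((table[col] >= 1) & (table[col] <= table["n_lesions"])).all()

    def test_patient_with_identical_pair_row(self, default_profiles):
        frame = default_profiles.copy()
        dup = pd.DataFrame(
            np.tile(np.full(6, 0.5), (2, 1)),
            index=pd.MultiIndex.from_tuples(
                [("ZZZ", "L1"), ("ZZZ", "L2")], names=["patient_id", "lesion_id"]
            ),
            columns=frame.columns,
        )
        table = lf.tree_descriptor_table(pd.concat([frame, dup]))
        row = table.loc["ZZZ"]
        assert row["n_lesions"] == 2
        assert row["sum_branch_lengths"] == 0.0
        assert row["dispersion"] == 0.0
        assert (row[["n_phenotypes_silhouette", "n_phenotypes_ch", "n_phenotypes_db"]] == 1).all()

    def test_recomputation_is_idempotent(self, default_profiles):
        a = lf.tree_descriptor_table(default_profiles)
        b = lf.tree_descriptor_table(default_profiles)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_pairwise_distance_alternative(self, rng):
        X = rng.uniform(0, 1, (5, 6))
        D = lf.pairwise_distance_matrix(X)
        assert mean_pairwise_distance(X) == pytest.approx(
            D[np.triu_indices(5, 1)].mean()
        )

    def test_trees_cover_all_patients(self, default_profiles):
        trees = build_patient_trees(default_profiles)
        assert set(trees) == set(default_profiles.index.get_level_values(0))
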