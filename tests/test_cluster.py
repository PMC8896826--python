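"""Threshold clustering, subclustering, and representative selection."""

import functools
import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

import phylorep as pr
from phylorep.cluster import (
    pick_representatives,
    plan_subclusters,
    sample_tree,
    subcluster_count,
    threshold_clusters,
)
from phylorep.tree import PatristicMatrix
from conftest import random_trees


def min_clusters_exhaustive(matrix, threshold):
    """Oracle: minimum number of diameter-bounded parts, by bitmask DP."""
    n = matrix.n
    v = matrix.values

    @functools.lru_cache(maxsize=None)
    def diameter_ok(mask):
        idx = [i for i in range(n) if mask >> i & 1]
        return all(
            v[a, b] <= threshold + 1e-12 for a, b in itertools.combinations(idx, 2)
        )

    @functools.lru_cache(maxsize=None)
    def solve(mask):
        if mask == 0:
            return 0
        low = mask & -mask
        rest = mask ^ low
        best = n + 1
        sub = rest
        while True:
            cand = sub | low
            if diameter_ok(cand):
                best = min(best, 1 + solve(mask ^ cand))
            if sub == 0:
                break
            sub = (sub - 1) & rest
        return best

    return solve((1 << n) - 1)


def max_clade_exhaustive(tree, matrix, threshold):
    """Oracle: top-down clade recursion done independently on leaf sets."""
    out = []

    def diameter(leaves):
        idx = [matrix.index_of(x) for x in leaves]
        return max(
            (matrix.values[a, b] for a, b in itertools.combinations(idx, 2)),
            default=0.0,
        )

    def recurse(node):
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if node.is_leaf() or diameter(leaves) <= threshold:
            out.append(frozenset(leaves))
        else:
            for child in node.child_nodes():
                recurse(child)

    recurse(tree.root)
    return set(out)


class TestThresholdClusters:
    @pytest.mark.parametrize("mode", ["max", "max_clade"])
    def test_threshold_above_diameter_gives_one_cluster(self, four_leaf_tree, mode):
        mat = pr.patristic_matrix(four_leaf_tree)
        ca = threshold_clusters(four_leaf_tree, mat, mat.values.max() + 1, mode)
        assert ca.n_clusters == 1

    @pytest.mark.parametrize("mode", ["max", "max_clade"])
    def test_threshold_below_min_distance_gives_singletons(self, four_leaf_tree, mode):
        mat = pr.patristic_matrix(four_leaf_tree)
        off_diag = mat.values[~np.eye(mat.n, dtype=bool)]
        ca = threshold_clusters(four_leaf_tree, mat, off_diag.min() / 2, mode)
        assert ca.n_clusters == mat.n

    def test_two_cherries_split_cleanly(self, cherry_pair_tree):
        mat = pr.patristic_matrix(cherry_pair_tree)
        ca = threshold_clusters(cherry_pair_tree, mat, 3, "max")
        groups = {frozenset(c) for c in ca.clusters()}
        assert groups == {frozenset("AB"), frozenset("CD")}
        # brute force confirms 2 is the minimum
        assert min_clusters_exhaustive(mat, 3) == 2

    def test_invalid_threshold_and_mode(self, four_leaf_tree, four_leaf_matrix):
        with pytest.raises(ValueError, match="threshold"):
            threshold_clusters(four_leaf_tree, four_leaf_matrix, 0)
        with pytest.raises(ValueError, match="mode"):
            threshold_clusters(four_leaf_tree, four_leaf_matrix, 1, "sum_branch")

    def test_max_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(5)
        for tree in random_trees(25, 4, 10, seed0=500):
            mat = pr.patristic_matrix(tree)
            thr = float(rng.uniform(0.05, mat.values.max() * 1.2))
            ca = threshold_clusters(tree, mat, thr, "max")
            for cluster in ca.clusters():
                idx = [mat.index_of(x) for x in cluster]
                assert all(
                    mat.values[a, b] <= thr + 1e-12
                    for a, b in itertools.combinations(idx, 2)
                )
            assert ca.n_clusters == min_clusters_exhaustive(mat, thr)

    def test_max_clade_matches_clade_recursion_oracle(self):
        rng = np.random.default_rng(6)
        for tree in random_trees(25, 4, 10, seed0=900):
            mat = pr.patristic_matrix(tree)
            thr = float(rng.uniform(0.05, mat.values.max() * 1.2))
            ca = threshold_clusters(tree, mat, thr, "max_clade")
            assert {frozenset(c) for c in ca.clusters()} == max_clade_exhaustive(
                tree, mat, thr
            )

    def test_partition_invariant_and_contiguous_ids(self):
        for tree in random_trees(5, 5, 20, seed0=77):
            mat = pr.patristic_matrix(tree)
            ca = threshold_clusters(tree, mat, 1.0, "max_clade")
            assert sorted(ca.assignment) == sorted(tree.leaf_labels)
            assert sorted(set(ca.assignment.values())) == list(
                range(1, ca.n_clusters + 1)
            )

    def test_max_clade_cluster_count_monotone_in_threshold(self):
        for tree in random_trees(5, 8, 25, seed0=303):
            mat = pr.patristic_matrix(tree)
            counts = [
                threshold_clusters(tree, mat, t, "max_clade").n_clusters
                for t in np.linspace(0.05, mat.values.max() + 0.1, 12)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


def toy_matrix(labels, pairs):
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    values = np.zeros((n, n))
    for (a, b), d in pairs.items():
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = d
    return PatristicMatrix(list(labels), values)


class TestPlanSubclusters:
    def test_target_count_arithmetic(self):
        assert subcluster_count(1, 0.2) == 1
        assert subcluster_count(10, 0.2) == 2
        assert subcluster_count(3, 1.0) == 3
        assert subcluster_count(5, 0.2) == 1
        assert subcluster_count(6, 0.2) == 2

    def test_singleton_cluster(self, four_leaf_matrix):
        plan = plan_subclusters([["A"]], four_leaf_matrix, fraction=0.2)
        assert plan.subclusters[1] == [["A"]]

    def test_close_pair_groups_against_outlier(self):
        # brute force over 2-partitions: {A,B} vs {C} minimises merge height
        mat = toy_matrix("ABC", {("A", "B"): 1, ("A", "C"): 10, ("B", "C"): 10})
        plan = plan_subclusters([["A", "B", "C"]], mat, fraction=0.5)
        assert plan.subclusters[1] == [["A", "B"], ["C"]]

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_matches_scipy_cut_on_tiefree_data(self, linkage):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            # random tie-free metric via random points on a line
            pts = np.sort(rng.normal(size=n) * 10)
            labels = [f"L{i:02d}" for i in range(n)]
            values = np.abs(pts[:, None] - pts[None, :])
            mat = PatristicMatrix(labels, values)
            k = int(rng.integers(2, n))
            plan = plan_subclusters([labels], mat, fraction=k / n, linkage=linkage)
            z = sch.linkage(squareform(values), method=linkage)
            want_k = subcluster_count(n, k / n)
            ref = sch.cut_tree(z, n_clusters=want_k).ravel()
            ref_groups = {
                frozenset(labels[i] for i in np.flatnonzero(ref == g))
                for g in np.unique(ref)
            }
            got_groups = {frozenset(g) for g in plan.subclusters[1]}
            assert got_groups == ref_groups

    def test_invalid_fraction_and_empty_cluster(self, four_leaf_matrix):
        with pytest.raises(ValueError, match="fraction"):
            plan_subclusters([["A"]], four_leaf_matrix, fraction=0)
        with pytest.raises(ValueError, match="empty"):
            plan_subclusters([[]], four_leaf_matrix, fraction=0.2)


class TestPickRepresentatives:
    def test_priority_wins(self, four_leaf_matrix):
        plan = plan_subclusters([["A", "B"]], four_leaf_matrix, fraction=0.2)
        reps = pick_representatives(plan, four_leaf_matrix, priorities={"B": 2})
        assert reps.to_frame().iloc[0].tolist() == ["B", 1, 1, "priority"]

    def test_medoid_breaks_rank_ties(self):
        mat = toy_matrix("ABC", {("A", "B"): 1, ("A", "C"): 2, ("B", "C"): 3})
        plan = plan_subclusters([["A", "B", "C"]], mat, fraction=0.1)
        reps = pick_representatives(plan, mat)
        # distance sums: A=3, B=4, C=5
        assert reps.to_frame().iloc[0].tolist() == ["A", 1, 1, "medoid"]

    def test_lexicographic_breaks_symmetric_pair(self):
        mat = toy_matrix("PQ", {("P", "Q"): 2})
        plan = plan_subclusters([["Q", "P"]], mat, fraction=0.1)
        reps = pick_representatives(plan, mat)
        assert reps.to_frame().iloc[0].tolist() == ["P", 1, 1, "lexicographic"]

    def test_one_representative_per_subcluster_membership(self):
        for tree in random_trees(4, 8, 20, seed0=88):
            mat = pr.patristic_matrix(tree)
            ca = threshold_clusters(tree, mat, 1.0, "max_clade")
            plan = plan_subclusters(ca, mat, fraction=0.3)
            reps = pick_representatives(plan, mat)
            assert len(reps) == plan.total_subclusters
            for rec in reps.records:
                members = plan.subclusters[rec.cluster][rec.subcluster - 1]
                assert rec.leaf_label in members


class TestSampleTree:
    def test_one_leaf_cluster_trivial(self):
        tree = pr.parse_newick("(A:1,B:5);")
        reps, prov = sample_tree(tree, threshold=0.5, fraction=1.0)
        assert sorted(reps.labels) == ["A", "B"]

    def test_fraction_one_selects_all_leaves(self, four_leaf_tree):
        mat = pr.patristic_matrix(four_leaf_tree)
        reps, _ = sample_tree(
            four_leaf_tree, threshold=mat.values.max() + 1, fraction=1.0
        )
        assert sorted(reps.labels) == sorted(four_leaf_tree.leaf_labels)

    def test_equals_composition_of_stages(self):
        from phylorep.simulate import simulate_yule_tree

        tree = simulate_yule_tree(12, seed=21)
        mat = pr.patristic_matrix(tree)
        reps, prov = sample_tree(tree, threshold=1.0, fraction=0.4)
        ca = threshold_clusters(tree, mat, 1.0, "max_clade")
        plan = plan_subclusters(ca, mat, fraction=0.4)
        expect = pick_representatives(plan, mat)
        assert reps.to_frame().equals(expect.to_frame())
        assert prov["n_selected"] == sum(
            subcluster_count(len(c), 0.4) for c in ca.clusters()
        )

    def test_deterministic_tsv_output(self, tmp_path):
        from phylorep.simulate import simulate_yule_tree

        tree = simulate_yule_tree(30, seed=4)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        sample_tree(tree, threshold=1.2, fraction=0.25)[0].to_tsv(p1)
        sample_tree(tree, threshold=1.2, fraction=0.25)[0].to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
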