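"""Distances, Lance-Williams agglomeration, tree cutting, grid search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from _oracles import naive_agglomerate, naive_cut
from prognomics.cluster import (
    LINKAGES,
    METRICS,
    ClusterGridSpec,
    DistanceSpec,
    cluster_of_clusters,
    cut_tree,
    grid_search,
    hierarchical_cluster,
    one_hot_cluster_matrix,
    pairwise_distance,
)
from prognomics.config import EvalConfig
from prognomics.datatypes import ClusterLabels, SurvivalData


class TestDistances:
    def test_hand_computed_values(self):
        x = np.array([[1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        assert pairwise_distance(x, DistanceSpec("binary"))[0, 1] == pytest.approx(2 / 3)
        y = np.array([[0.0, 3.0, 4.0], [0.0, 0.0, 0.0]])
        assert pairwise_distance(y, DistanceSpec("euclidean"))[0, 1] == pytest.approx(5.0)
        assert pairwise_distance(y, DistanceSpec("manhattan"))[0, 1] == pytest.approx(7.0)
        assert pairwise_distance(y, DistanceSpec("maximum"))[0, 1] == pytest.approx(4.0)
        assert pairwise_distance(y, DistanceSpec("canberra"))[0, 1] == pytest.approx(2.0)

    def test_minkowski_p3_and_correlation(self):
        x = np.array([[0.0, 0.0], [1.0, 2.0]])
        expected = (1.0 + 8.0) ** (1 / 3)
        assert pairwise_distance(x, DistanceSpec("minkowski", 3.0))[0, 1] == pytest.approx(expected)
        z = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert pairwise_distance(z, DistanceSpec("correlation"))[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("metric", METRICS)
    def test_metric_axioms(self, metric):
        rng = np.random.default_rng(11)
        X = np.abs(rng.normal(size=(10, 6)))
        X[X < 0.3] = 0.0
        X[3] = X[0]  # identical pair
        D = pairwise_distance(X, DistanceSpec(metric))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert np.all(D >= -1e-12)
        assert D[0, 3] == pytest.approx(0.0, abs=1e-12)
        if metric in ("euclidean", "manhattan", "maximum", "minkowski"):
            for i in range(10):
                for j in range(10):
                    for k in range(10):
                        assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_correlation_rejects_zero_variance_row(self, matrix_factory):
        m = matrix_factory(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="S0"):
            pairwise_distance(m, DistanceSpec("correlation"))

    def test_na_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="impute or filter"):
            pairwise_distance(X, DistanceSpec("euclidean"))


class TestHierarchicalCluster:
    def test_three_point_single_linkage_hand_example(self):
        D = pairwise_distance(np.array([[0.0], [1.0], [10.0]]), DistanceSpec("euclidean"))
        tree = hierarchical_cluster(D, "single")
        assert tree.merges[0][:2] == (0, 1)
        assert tree.merges[0][2] == pytest.approx(1.0)
        assert tree.merges[1][2] == pytest.approx(9.0)
        assert list(cut_tree(tree, 2).labels) == [1, 1, 2]

    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_two_points_merge_at_pairwise_distance(self, linkage):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        tree = hierarchical_cluster(D, linkage)
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == pytest.approx(3.0)

    def test_partition_agrees_with_naive_oracle_average(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(20, 4))
        D = pairwise_distance(X, DistanceSpec("euclidean"))
        tree = hierarchical_cluster(D, "average")
        merges = naive_agglomerate(D, "average")
        for k in range(1, 21):
            mine = cut_tree(tree, k).labels
            theirs = naive_cut(merges, 20, k)
            assert adjusted_rand_score(mine, theirs) == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(15, 5))
        D = pairwise_distance(X, DistanceSpec("manhattan"))
        perm = rng.permutation(15)
        Dp = D[np.ix_(perm, perm)]
        for linkage in ("average", "complete", "ward_d"):
            lab = cut_tree(hierarchical_cluster(D, linkage), 4).labels
            lab_p = cut_tree(hierarchical_cluster(Dp, linkage), 4).labels
            unpermuted = np.empty(15, dtype=int)
            unpermuted[perm] = lab_p
            assert adjusted_rand_score(lab, unpermuted) == 1.0

    def test_cut_tree_nested_partitions(self):
        rng = np.random.default_rng(23)
        D = pairwise_distance(rng.normal(size=(18, 3)), DistanceSpec("euclidean"))
        for linkage in LINKAGES:
            tree = hierarchical_cluster(D, linkage)
            prev = cut_tree(tree, 18).labels
            for k in range(17, 0, -1):
                cur = cut_tree(tree, k).labels
                # every cluster at k+1 maps inside exactly one cluster at k
                for lab in np.unique(prev):
                    assert len(np.unique(cur[prev == lab])) == 1
                prev = cur

    def test_cut_tree_bounds(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        tree = hierarchical_cluster(D, "single")
        assert list(cut_tree(tree, 2).labels) == [1, 2]
        assert list(cut_tree(tree, 1).labels) == [1, 1]
        with pytest.raises(ValueError):
            cut_tree(tree, 3)
        with pytest.raises(ValueError):
            cut_tree(tree, 0)


class TestOneHot:
    def test_column_count_and_row_sums(self):
        a = ClusterLabels(np.array([1, 2, 1, 2]), 2, ("euclidean", "average", 2), name="A")
        b = ClusterLabels(np.array([1, 2, 3, 1]), 3, ("euclidean", "average", 3), name="B")
        m = one_hot_cluster_matrix([a, b])
        assert m.n_features == 5
        assert np.all(m.values.sum(axis=1) == 2)
        assert m.layer == "cluster_binary" and m.scale == "binary"

    def test_single_set_rows(self):
        a = ClusterLabels(np.array([1, 2, 1]), 2, ("x", "y", 2), name="L")
        m = one_hot_cluster_matrix([a])
        assert m.values.to_numpy().tolist() == [[1, 0], [0, 1], [1, 0]]

    def test_paper_scale_4_10_4_gives_18_columns(self):
        rng = np.random.default_rng(1)
        sets = []
        for name, k in (("G", 4), ("M", 10), ("m", 4)):
            labels = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, 40 - k)])
            sets.append(ClusterLabels(labels, k, ("d", "l", k), name=name))
        assert one_hot_cluster_matrix(sets).n_features == 18

    def test_mismatched_lengths_rejected(self):
        a = ClusterLabels(np.array([1, 2]), 2, ("d", "l", 2), name="A")
        b = ClusterLabels(np.array([1, 2, 2]), 2, ("d", "l", 2), name="B")
        with pytest.raises(ValueError, match="share sample order"):
            one_hot_cluster_matrix([a, b])


class TestGridSearch:
    def _survival_with_signal(self, labels, seed=0):
        rng = np.random.default_rng(seed)
        lp = 0.9 * (labels - np.mean(labels))
        T = rng.exponential(np.exp(-lp))
        C = rng.uniform(0, 4.0, len(labels))
        return SurvivalData(np.minimum(T, C), (T <= C).astype(int))

    def test_no_feasible_candidate_raises(self):
        # n=19: any 2-way split has a side with <10 members
        rng = np.random.default_rng(31)
        X = rng.normal(size=(19, 4))
        surv = self._survival_with_signal(rng.integers(0, 2, 19))
        grid = ClusterGridSpec(distances=("euclidean",), linkages=("average",),
                               k_range=(2, 2), min_cluster_size=10)
        with pytest.raises(ValueError, match="no feasible candidate"):
            grid_search(X, surv, None, grid, EvalConfig(search_B=10, seed=0))

    def test_candidate_count_and_infeasible_marking(self):
        rng = np.random.default_rng(32)
        X = np.vstack([rng.normal(0, 1, size=(30, 4)), rng.normal(5, 1, size=(30, 4))])
        labels_true = np.repeat([0, 1], 30)
        surv = self._survival_with_signal(labels_true, seed=1)
        grid = ClusterGridSpec(distances=("euclidean", "manhattan"), linkages=("average",),
                               k_range=(2, 5), min_cluster_size=10)
        res = grid_search(X, surv, None, grid, EvalConfig(search_B=20, seed=0))
        assert len(res.candidates) == 2 * 1 * 4
        infeasible = [c for c in res.candidates if not c.feasible]
        for c in infeasible:
            assert c.labels is None or c.labels.sizes().min() < 10 or c.reason
        # winner is feasible with the max score
        feasible = [c for c in res.candidates if c.feasible]
        best = max(c.score for c in feasible)
        winner = next(c for c in feasible if c.params == res.winner)
        assert winner.score == best

    def test_two_planted_groups_recovered(self):
        rng = np.random.default_rng(33)
        n = 100
        truth = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 10)) + truth[:, None] * 3.0
        surv = self._survival_with_signal(truth * 1.5, seed=2)
        grid = ClusterGridSpec(distances=("euclidean",), linkages=("average",),
                               k_range=(2, 5), min_cluster_size=10)
        res = grid_search(X, surv, None, grid, EvalConfig(search_B=30, seed=0))
        assert res.winner[2] == 2
        assert adjusted_rand_score(res.winner_labels.labels, truth) >= 0.9

    def test_candidate_score_independent_of_evaluation_position(self):
        """Every candidate consumes the same bootstrap index stream, so
        its score does not depend on where in the grid it is evaluated."""
        rng = np.random.default_rng(34)
        n = 80
        truth = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 6)) + truth[:, None] * 2.5
        surv = self._survival_with_signal(truth, seed=3)
        cfg = EvalConfig(search_B=20, seed=5)
        full = ClusterGridSpec(distances=("euclidean", "manhattan"), linkages=("average",),
                               k_range=(2, 4), min_cluster_size=10)
        solo = ClusterGridSpec(distances=("manhattan",), linkages=("average",),
                               k_range=(2, 2), min_cluster_size=10)
        r_full = grid_search(X, surv, None, full, cfg)
        r_solo = grid_search(X, surv, None, solo, cfg)
        in_full = next(c for c in r_full.candidates if c.params == ("manhattan", "average", 2))
        assert in_full.score == r_solo.candidates[0].score
        # and the whole search is deterministic
        r_again = grid_search(X, surv, None, full, cfg)
        assert r_again.winner == r_full.winner
        assert [c.score for c in r_again.candidates] == [c.score for c in r_full.candidates]


class TestClusterOfClusters:
    def test_identical_partitions_reproduced(self):
        rng = np.random.default_rng(41)
        # blocks of 15: any split of a block leaves a cluster under 10
        # patients, so only the block partition itself is feasible at k=3
        n = 45
        part = np.repeat([1, 2, 3], n // 3)
        sets = [ClusterLabels(part, 3, ("d", "l", 3), name=nm) for nm in ("G", "M", "m")]
        surv_rng = np.random.default_rng(42)
        lp = 0.8 * (part - 2)
        T = surv_rng.exponential(np.exp(-lp))
        C = surv_rng.uniform(0, 4, n)
        surv = SurvivalData(np.minimum(T, C), (T <= C).astype(int))
        grid = ClusterGridSpec(distances=("euclidean",), linkages=("average",),
                               k_range=(2, 4), min_cluster_size=10)
        res = cluster_of_clusters(sets, surv, None, grid, EvalConfig(search_B=20, seed=0))
        assert res.winner[2] == 3
        assert adjusted_rand_score(res.winner_labels.labels, part) == 1.0
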