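import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from enmecotype.cluster import (LINKAGES, agglomerative_coefficient, choose_k,
                                cut_assign, ecotype_maps, hac, row_distance,
                                select_linkage)
from enmecotype.maxent import SuitabilityMap
from enmecotype.similarity import SimilarityMatrix


def _sim(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"p{i}" for i in range(len(values))]
    return SimilarityMatrix(labels=labels, values=values, metric="overlap_I")


def _block_distance(sizes, within=0.1, between=5.0, rng=None):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between)
    np.fill_diagonal(d, 0.0)
    if rng is not None:
        jitter = rng.uniform(0, 0.01, (n, n))
        jitter = (jitter + jitter.T) / 2
        np.fill_diagonal(jitter, 0.0)
        d = d + jitter
    return d, labels


class TestRowDistance:
    def test_identical_rows_have_zero_distance(self):
        s = _sim([[1.0, 0.5, 0.5], [0.5, 1.0, 1.0], [0.5, 1.0, 1.0]])
        d = row_distance(s)
        assert d.iloc[1, 2] == pytest.approx(0.0)

    def test_single_differing_coordinate_hand_value(self):
        rows = np.array([[1.0, 0.5, 0.0], [1.0, 0.5, 1.0]])
        # embed as a 2x3 "similarity" slab is not square; use direct rows via
        # a square matrix whose first two rows differ in one coordinate
        s = _sim([[1.0, 0.5, 0.0], [1.0, 0.5, 1.0], [0.0, 1.0, 1.0]])
        d = row_distance(s)
        expected = np.sqrt(((rows[0] - rows[1]) ** 2).sum())
        assert d.iloc[0, 1] == pytest.approx(expected) == pytest.approx(1.0)

    def test_symmetric_with_zero_diagonal(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, (5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        d = row_distance(_sim(v)).to_numpy()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_non_square_rejected(self):
        s = SimilarityMatrix(labels=["a", "b"],
                             values=np.ones((2, 3)), metric="overlap_I")
        with pytest.raises(ValueError):
            row_distance(s)


class TestHac:
    def test_hand_traced_single_linkage_on_three_points(self):
        # 1-D points {0, 1, 10}: merges at heights 1 then 9
        d = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 9.0], [10.0, 9.0, 0.0]])
        tree = hac(d, "single")
        np.testing.assert_allclose(tree.merges[:, 2], [1.0, 9.0])
        # AC = mean(1-1/9, 1-1/9, 1-9/9) = 16/27
        assert tree.ac == pytest.approx(16 / 27, abs=1e-12)

    def test_identical_objects_merge_at_height_zero(self):
        d = np.array([[0.0, 0.0, 2.0], [0.0, 0.0, 2.0], [2.0, 2.0, 0.0]])
        tree = hac(d, "average")
        assert tree.merges[0, 2] == pytest.approx(0.0)

    def test_ac_in_unit_interval_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = rng.integers(3, 12)
            v = rng.uniform(0.1, 5, (n, n))
            d = (v + v.T) / 2
            np.fill_diagonal(d, 0.0)
            for method in LINKAGES:
                tree = hac(d, method)
                assert 0.0 <= tree.ac <= 1.0

    def test_ac_matches_brute_force_recomputation_from_tree(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0.5, 3, (8, 8))
        d = (v + v.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = hac(d, "ward")
        # brute force: walk the merge list, note each leaf's first merge height
        n = 8
        first = {}
        members = {i: {i} for i in range(n)}
        for step, (a, b, h, _) in enumerate(tree.merges):
            leaves = members[int(a)] | members[int(b)]
            for leaf in members[int(a)] | members[int(b)]:
                first.setdefault(leaf, h)
            members[n + step] = leaves
        brute = np.mean([1 - first[i] / tree.merges[-1, 2] for i in range(n)])
        assert agglomerative_coefficient(tree.merges, n) == pytest.approx(brute)

    def test_invariant_to_label_permutation(self):
        rng = np.random.default_rng(3)
        d, labels = _block_distance([3, 3], rng=rng)
        names = [f"p{i}" for i in range(6)]
        df = pd.DataFrame(d, index=names, columns=names)
        t1 = cut_assign(hac(df, "ward"), 2)
        perm = ["p4", "p1", "p5", "p0", "p2", "p3"]
        t2 = cut_assign(hac(df.loc[perm, perm], "ward"), 2)
        a1 = [t1.assignment[p] for p in names]
        a2 = [t2.assignment[p] for p in names]
        assert adjusted_rand_score(a1, a2) == 1.0

    def test_single_object_rejected(self):
        with pytest.raises(ValueError):
            hac(np.zeros((1, 1)), "ward")


class TestLinkageChoice:
    def _tree(self, method, ac):
        t = hac(np.array([[0.0, 1.0], [1.0, 0.0]]), method)
        t.ac = ac
        return t

    def test_largest_ac_wins(self):
        trees = {"single": self._tree("single", 0.3),
                 "ward": self._tree("ward", 0.8)}
        assert select_linkage(trees) == "ward"

    def test_tie_prefers_ward_over_average(self):
        trees = {"average": self._tree("average", 0.7),
                 "ward": self._tree("ward", 0.7)}
        assert select_linkage(trees) == "ward"

    def test_single_tree_returns_itself(self):
        assert select_linkage({"complete": self._tree("complete", 0.1)}) == "complete"


class TestCutAndChooseK:
    def test_k_equals_n_gives_singletons(self):
        d, _ = _block_distance([2, 2])
        tree = hac(d, "ward")
        assign = cut_assign(tree, 4)
        assert sorted(assign.assignment.values()) == [1, 2, 3, 4]

    def test_k_one_gives_single_cluster(self):
        d, _ = _block_distance([2, 2])
        assign = cut_assign(hac(d, "ward"), 1)
        assert set(assign.assignment.values()) == {1}

    def test_planted_two_blocks_recovered_exactly(self):
        rng = np.random.default_rng(4)
        d, labels = _block_distance([4, 4], rng=rng)
        assign = cut_assign(hac(d, "ward"), 2)
        got = [assign.assignment[p] for p in assign.assignment]
        assert adjusted_rand_score(labels, got) == 1.0

    def test_k_out_of_range_rejected(self):
        d, _ = _block_distance([2, 2])
        with pytest.raises(ValueError):
            cut_assign(hac(d, "ward"), 5)

    @pytest.mark.parametrize("sizes,expected", [([3, 3, 3, 3], 4), ([5, 5], 2)])
    def test_silhouette_finds_planted_block_count(self, sizes, expected):
        rng = np.random.default_rng(5)
        d, _ = _block_distance(sizes, rng=rng)
        tree = hac(d, "ward")
        assert choose_k(tree, d) == expected

    def test_config_override_wins(self):
        rng = np.random.default_rng(6)
        d, _ = _block_distance([5, 5], rng=rng)
        tree = hac(d, "ward")
        assert choose_k(tree, d, override=4) == 4


class TestEcotypeMaps:
    def _surf(self, values):
        v = np.asarray(values, dtype=float)
        return SuitabilityMap(raw=v / v.sum(), logistic=v, cumulative=v,
                              mask=np.isfinite(v))

    def test_singleton_cluster_keeps_member_map(self):
        maps = {"a": self._surf([[1.0, 2.0], [3.0, 4.0]]),
                "b": self._surf([[4.0, 3.0], [2.0, 1.0]])}
        tree = hac(np.array([[0.0, 1.0], [1.0, 0.0]]), "ward")
        tree.labels = ["a", "b"]
        assign = cut_assign(tree, 2)
        combined = ecotype_maps(maps, assign)
        assert len(combined) == 2
        np.testing.assert_array_equal(
            combined[assign.assignment["a"]], maps["a"].cumulative)

    def test_identical_members_combine_to_either(self):
        m = self._surf([[1.0, 2.0], [3.0, 4.0]])
        maps = {"a": m, "b": m}
        tree = hac(np.array([[0.0, 0.1], [0.1, 0.0]]), "ward")
        tree.labels = ["a", "b"]
        assign = cut_assign(tree, 1)
        combined = ecotype_maps(maps, assign)
        np.testing.assert_array_equal(combined[1], m.cumulative)

    def test_unassigned_population_rejected(self):
        m = self._surf([[1.0, 2.0], [3.0, 4.0]])
        tree = hac(np.array([[0.0, 0.1], [0.1, 0.0]]), "ward")
        tree.labels = ["a", "b"]
        assign = cut_assign(tree, 1)
        with pytest.raises(ValueError):
            ecotype_maps({"a": m, "c": m}, assign)
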