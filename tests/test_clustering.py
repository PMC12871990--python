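"""Hierarchical clustering (four linkages), dendrogram cuts and tree purity."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

import cellph as cp
from cellph.errors import DomainError, ParameterError
from cellph.wasserstein import DistanceMatrix


def dm_from_points_1d(points):
    pts = np.asarray(points, float)
    vals = np.abs(pts[:, None] - pts[None, :])
    return DistanceMatrix(tuple(str(p) for p in points), vals)


def random_dm(rng, n):
    v = rng.uniform(0.1, 10, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return DistanceMatrix(tuple(f"c{i}" for i in range(n)), v)


def cophenetic(tree: cp.Dendrogram) -> np.ndarray:
    """First-merge height for every leaf pair (from our merge list)."""
    n = tree.n_leaves
    members = {i: {i} for i in range(n)}
    out = np.zeros((n, n))
    for a, b, h, new in tree.merges:
        for i in members[a]:
            for j in members[b]:
                out[i, j] = out[j, i] = h
        members[new] = members.pop(a) | members.pop(b)
    return out


def naive_hca(m: DistanceMatrix, linkage: str) -> list:
    """Literal O(n^3) re-scan of all active cluster pairs at every step."""
    d = m.values
    clusters = {i: [i] for i in range(len(m))}

    def dist(A, B):
        block = d[np.ix_(A, B)]
        if linkage == "average":
            return block.mean()
        if linkage == "single":
            return block.min()
        if linkage == "complete":
            return block.max()

        def sse(C):
            sub = d[np.ix_(C, C)]
            return np.sum(sub[int(np.argmin(sub.sum(axis=1)))] ** 2)

        return sse(A + B) - sse(A) - sse(B)

    merges, next_id = [], len(m)
    while len(clusters) > 1:
        best = min(
            (dist(clusters[i], clusters[j]), i, j)
            for i in clusters
            for j in clusters
            if i < j
        )
        h, i, j = best
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        merges.append((i, j, h, next_id))
        next_id += 1
    return merges


def purity_walk(c1_leaves, tree: cp.Dendrogram, seed_leaf):
    """Literal seed-walk: climb parents, absorbing subtrees, until C1 covered."""
    members, parents = tree.members(), tree.parents()
    O = {seed_leaf}
    node = seed_leaf
    while not c1_leaves <= O:
        node = parents[node]
        O |= members[node]
    return O


class TestHca:
    @pytest.mark.parametrize(
        "linkage,heights",
        [("single", [1, 4]), ("complete", [1, 5]), ("average", [1, 4.5])],
    )
    def test_three_point_line_merge_heights(self, linkage, heights):
        tree = cp.hca(dm_from_points_1d([0, 1, 5]), linkage)
        assert [m[2] for m in tree.merges] == pytest.approx(heights)
        assert tree.merges[0][:2] == (0, 1)

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_on_random_matrices(self, linkage, seed):
        rng = np.random.default_rng(seed)
        m = random_dm(rng, int(rng.integers(4, 11)))
        ours = cp.hca(m, linkage)
        ref = hierarchy.linkage(squareform(m.values), method=linkage)
        np.testing.assert_allclose(
            sorted(mg[2] for mg in ours.merges), sorted(ref[:, 2]), rtol=1e-12
        )
        ref_coph = squareform(hierarchy.cophenet(ref))
        np.testing.assert_allclose(cophenetic(ours), ref_coph, rtol=1e-12)

    @pytest.mark.parametrize("linkage", cp.LINKAGES)
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_rescan_all_linkages(self, linkage, seed):
        rng = np.random.default_rng(100 + seed)
        m = random_dm(rng, 9)
        ours = cp.hca(m, linkage).merges
        ref = naive_hca(m, linkage)
        assert [mg[:2] for mg in ours] == [tuple(mg[:2]) for mg in ref]
        np.testing.assert_allclose([mg[2] for mg in ours], [mg[2] for mg in ref], rtol=1e-12)

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(Exception):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0.0]]))


class TestCut:
    def test_k_extremes(self):
        m = dm_from_points_1d([0, 1, 5, 6])
        tree = cp.hca(m, "single")
        assert set(cp.cut(tree, 1).labels.values()) == {"A"}
        assert len(set(cp.cut(tree, 4).labels.values())) == 4

    def test_two_cluster_cut_of_line(self):
        tree = cp.hca(dm_from_points_1d([0, 1, 5]), "single")
        groups = cp.cut(tree, 2).groups()
        assert groups == {"A": ("0", "1"), "B": ("5",)}

    def test_k_out_of_range(self):
        tree = cp.hca(dm_from_points_1d([0, 1, 5]), "single")
        with pytest.raises(ParameterError):
            cp.cut(tree, 0)
        with pytest.raises(ParameterError):
            cp.cut(tree, 4)

    def test_names_ordered_by_size(self):
        rng = np.random.default_rng(0)
        m = random_dm(rng, 8)
        groups = cp.cut(cp.hca(m, "average"), 3).groups()
        sizes = [len(groups[name]) for name in sorted(groups)]
        assert sizes == sorted(sizes, reverse=True)


class TestPurity:
    def test_pure_subtree_scores_one(self):
        tree = cp.hca(dm_from_points_1d([0, 1, 5, 6, 20]), "single")
        assert cp.purity({"0", "1"}, tree) == 1.0
        assert cp.purity({"20"}, tree) == 1.0  # singleton cluster is its own leaf

    def test_root_subtree_scores_zero(self):
        tree = cp.hca(dm_from_points_1d([0, 1, 5, 6, 20]), "single")
        assert cp.purity({"0", "20"}, tree) == 0.0

    def test_purity_formula_arithmetic(self):
        # 10 leaves; c1 of size 4 whose LCA subtree holds 6 leaves -> (10-6)/(10-4)
        pts = [0, 1, 2, 3, 4.2, 5.2, 50, 60, 70, 80]
        tree = cp.hca(dm_from_points_1d(pts), "single")
        score = cp.purity({"0", "1", "4.2", "5.2"}, tree)
        assert score == pytest.approx(4 / 6)

    def test_full_leaf_set_is_undefined(self):
        tree = cp.hca(dm_from_points_1d([0, 1, 5]), "single")
        with pytest.raises(DomainError):
            cp.purity({"0", "1", "5"}, tree)

    @pytest.mark.parametrize("seed", range(10))
    def test_closed_form_equals_walk_from_every_seed(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        m = random_dm(rng, n)
        tree = cp.hca(m, "average")
        size = int(rng.integers(1, n))
        leaves = set(rng.choice(n, size=size, replace=False).tolist())
        ids = {tree.leaf_ids[i] for i in leaves}
        members = tree.members()
        # closed form: leaves of the LCA subtree
        node = min(leaves)
        parents = tree.parents()
        while not leaves <= members[node]:
            node = parents[node]
        expected_O = members[node]
        for seed_leaf in leaves:
            assert purity_walk(leaves, tree, seed_leaf) == expected_O
        assert cp.purity(ids, tree) == pytest.approx((n - len(expected_O)) / (n - size))

    @pytest.mark.parametrize("linkage", cp.LINKAGES)
    def test_own_tree_clusters_are_pure(self, linkage):
        rng = np.random.default_rng(5)
        m = random_dm(rng, 14)
        tree = cp.hca(m, linkage)
        for members in cp.cut(tree, 4).groups().values():
            assert cp.purity(set(members), tree) == 1.0


class TestSerialization:
    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        tree = cp.hca(dm_from_points_1d([0, 1, 5, 6]), "average")
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == {"0", "1", "5", "6"}
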