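"""Membership matrix construction, filtering, and deterministic bi-clustering."""

import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from co_atlas import biclustering as bc
from co_atlas import fixtures


def float_agglomerate(labels, vectors, distance="jaccard", linkage="average"):
    """Naive float-arithmetic oracle with the same lexicographic tie rule:
    at each step recompute every active cluster-pair distance directly from
    the leaf vectors and merge the minimum."""
    vectors = np.asarray(vectors, dtype=bool)
    leaf = {l: vectors[i] for i, l in enumerate(labels)}

    def leaf_dist(a, b):
        u, v = leaf[a], leaf[b]
        if distance == "jaccard":
            union = (u | v).sum()
            return (union - (u & v).sum()) / union
        return (u != v).sum() / len(u)

    def cluster_dist(c1, c2):
        ds = [leaf_dist(a, b) for a in c1 for b in c2]
        if linkage == "average":
            return float(np.mean(ds))
        return max(ds) if linkage == "complete" else min(ds)

    active = [frozenset({l}) for l in labels]
    merges = []
    while len(active) > 1:
        candidates = [
            (cluster_dist(a, b), tuple(sorted((min(a), min(b)))), a, b)
            for a, b in itertools.combinations(active, 2)
        ]
        d, _, a, b = min(candidates, key=lambda t: (t[0], t[1]))
        left, right = (a, b) if min(a) < min(b) else (b, a)
        merges.append((left, right, d))
        active = [c for c in active if c not in (a, b)] + [a | b]
    return merges


def random_binary_matrix(rng, n_rows, n_cols):
    """Binary matrix with no all-zero rows or columns (Jaccard-safe)."""
    while True:
        values = (rng.random((n_rows, n_cols)) < 0.45).astype(np.int8)
        if values.any(axis=1).all() and values.any(axis=0).all():
            return values


class TestBuildMatrix:
    def test_single_pathway_ones(self):
        m = bc.build_matrix({"P": {"A", "B"}}, {"A", "B", "C"})
        assert m.genes == ("A", "B") and m.values.sum() == 2

    def test_universe_restricts_rows(self):
        m = bc.build_matrix({"P": {"A", "B", "Z"}}, {"A", "B", "C"})
        assert m.genes == ("A", "B")

    def test_disjoint_lists_give_unit_row_sums(self):
        m = bc.build_matrix({"P1": {"A", "B"}, "P2": {"C"}})
        assert set(m.row_sums.values()) == {1}

    def test_combined_cohort_matrix_hras_participation(self):
        m = bc.build_matrix(
            fixtures.pathway_gene_lists(fixtures.table4_pathways()),
            fixtures.combined_cohort(),
        )
        assert m.row_sums["HRAS"] == 7


class TestFilterMinPathways:
    def test_zero_threshold_is_identity(self):
        m = bc.build_matrix({"P1": {"A", "B"}, "P2": {"B"}})
        assert bc.filter_min_pathways(m, 0) == m

    def test_all_ones_unchanged(self):
        m = bc.MembershipMatrix(("A", "B", "C"), ("P", "Q", "R"),
                                np.ones((3, 3), dtype=np.int8))
        assert bc.filter_min_pathways(m, 2) == m

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(8)
        m = bc.MembershipMatrix(
            tuple(f"g{i}" for i in range(10)),
            tuple(f"p{j}" for j in range(5)),
            random_binary_matrix(rng, 10, 5),
        )
        previous = set(m.genes)
        for threshold in range(5):
            filtered = bc.filter_min_pathways(m, threshold)
            assert bc.filter_min_pathways(filtered, threshold) == filtered
            assert set(filtered.genes) <= previous
            previous = set(filtered.genes)


class TestAgglomerate:
    def test_identical_rows_merge_first_at_zero(self):
        tree = bc.agglomerate(
            ["a", "b", "c"], np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        )
        left, right, height = tree.merges[0]
        assert {min(left), min(right)} == {"a", "b"} and height == 0.0

    def test_toy_matrix_first_merge_and_oracle_heights(self):
        labels = ["r1", "r2", "r3", "r4"]
        vectors = np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1], [1, 0, 1]])
        tree = bc.agglomerate(labels, vectors)
        assert tree.merges[0][:2] == (frozenset({"r1"}), frozenset({"r2"}))
        oracle = float_agglomerate(labels, vectors)
        for (l1, r1_, h1), (l2, r2_, h2) in zip(tree.merges, oracle):
            assert (l1, r1_) == (l2, r2_)
            assert h1 == pytest.approx(h2)

    def test_row_order_permutation_invariant(self):
        rng = np.random.default_rng(17)
        values = random_binary_matrix(rng, 7, 4)
        labels = [f"g{i}" for i in range(7)]
        tree = bc.agglomerate(labels, values)
        perm = rng.permutation(7)
        shuffled = bc.agglomerate(
            [labels[i] for i in perm], values[perm]
        )
        assert tree.merges == shuffled.merges
        assert tree.leaf_order() == shuffled.leaf_order()

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            values = random_binary_matrix(rng, 8, 5)
            tree = bc.agglomerate([f"g{i}" for i in range(8)], values)
            heights = [h for _, _, h in tree.merges]
            assert heights == sorted(heights)

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    @pytest.mark.parametrize("distance", ["jaccard", "hamming"])
    def test_matches_bruteforce_oracle_small_matrices(self, distance, linkage):
        rng = np.random.default_rng(31)
        for _ in range(12):
            n_rows = int(rng.integers(2, 7))
            n_cols = int(rng.integers(2, 7))
            values = random_binary_matrix(rng, n_rows, n_cols)
            labels = [f"g{i}" for i in range(n_rows)]
            tree = bc.agglomerate(labels, values, distance, linkage)
            oracle = float_agglomerate(labels, values, distance, linkage)
            assert [m[:2] for m in tree.merges] == [m[:2] for m in oracle]
            assert [m[2] for m in tree.merges] == pytest.approx(
                [m[2] for m in oracle]
            )

    def test_single_linkage_heights_match_scipy(self):
        # single-linkage merge heights equal the MST edge weights, which are
        # invariant under tie-breaking -- an implementation-independent check
        rng = np.random.default_rng(37)
        values = random_binary_matrix(rng, 9, 6)
        tree = bc.agglomerate(
            [f"g{i}" for i in range(9)], values, "jaccard", "single"
        )
        Z = hierarchy.linkage(pdist(values.astype(bool), "jaccard"), "single")
        assert sorted(h for _, _, h in tree.merges) == pytest.approx(
            sorted(Z[:, 2])
        )

    def test_zero_row_under_jaccard_is_error(self):
        with pytest.raises(ValueError, match="pre-filter"):
            bc.agglomerate(["a", "b"], np.array([[0, 0], [1, 0]]))


class TestBicluster:
    def test_transpose_swaps_trees(self):
        rng = np.random.default_rng(41)
        m = bc.MembershipMatrix(
            tuple(f"g{i}" for i in range(6)),
            tuple(f"p{j}" for j in range(4)),
            random_binary_matrix(rng, 6, 4),
        )
        rows, cols, _ = bc.bicluster(m)
        rows_t, cols_t, _ = bc.bicluster(m.transpose())
        assert rows.merges == cols_t.merges
        assert cols.merges == rows_t.merges

    def test_reordering_preserves_entries(self):
        rng = np.random.default_rng(43)
        m = bc.MembershipMatrix(
            tuple(f"g{i}" for i in range(6)),
            tuple(f"p{j}" for j in range(4)),
            random_binary_matrix(rng, 6, 4),
        )
        _, _, reordered = bc.bicluster(m)
        assert sorted(reordered.genes) == sorted(m.genes)
        assert sorted(reordered.pathways) == sorted(m.pathways)
        assert reordered.to_frame().loc[list(m.genes), list(m.pathways)].equals(
            m.to_frame()
        )

    def test_requires_two_rows_and_columns(self):
        m = bc.MembershipMatrix(("a",), ("p", "q"), np.array([[1, 1]]))
        with pytest.raises(ValueError):
            bc.bicluster(m)


class TestCutClusters:
    @pytest.fixture
    def tree(self):
        rng = np.random.default_rng(47)
        return bc.agglomerate(
            [f"g{i}" for i in range(6)], random_binary_matrix(rng, 6, 4)
        )

    def test_k_equals_leaves_gives_singletons(self, tree):
        assert bc.cut_clusters(tree, 6) == [{f"g{i}"} for i in range(6)]

    def test_k_one_gives_everything(self, tree):
        assert bc.cut_clusters(tree, 1) == [{f"g{i}" for i in range(6)}]

    def test_partition_covers_leaves_exactly_once(self, tree):
        for k in range(1, 7):
            parts = bc.cut_clusters(tree, k)
            assert len(parts) == k
            assert sorted(g for p in parts for g in p) == sorted(tree.leaves)

    def test_pathway_axis_splits_into_contraction_and_signaling_groups(self):
        """The 2-cut of the pathway dendrogram separates the muscle/cardiac
        contraction + cardiomyopathy block from the eight signaling-type
        pathways."""
        m = bc.build_matrix(
            fixtures.pathway_gene_lists(fixtures.table4_pathways()),
            fixtures.combined_cohort(),
        )
        filtered = bc.filter_min_pathways(m, 2)
        _, col_tree, _ = bc.bicluster(filtered)
        groups = bc.cut_clusters(col_tree, 2)
        contraction = {
            "REACTOME|Muscle contraction",
            "KEGG|Cardiac muscle contraction",
            "KEGG|Hypertrophic cardiomyopathy (HCM)",
            "KEGG|Dilated cardiomyopathy",
        }
        assert contraction in groups
        assert set(filtered.pathways) - contraction in groups


def test_newick_round_trips_heights(tmp_path):
    rng = np.random.default_rng(53)
    tree = bc.agglomerate(
        [f"g{i}" for i in range(5)], random_binary_matrix(rng, 5, 4)
    )
    text = tree.to_newick()
    assert text.endswith(";") and text.count("(") == len(tree.merges)
    for leaf in tree.leaves:
        assert leaf in text


def test_matrix_tsv_round_trip(tmp_path):
    m = bc.build_matrix(
        fixtures.pathway_gene_lists(fixtures.table4_pathways()),
        fixtures.combined_cohort(),
    )
    path = tmp_path / "matrix.tsv"
    bc.write_matrix(m, path)
    assert bc.read_matrix(path) == m
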