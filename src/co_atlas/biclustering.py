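"""Binary gene x pathway membership matrix and hierarchical bi-clustering.

Genes significant pathways share are summarized in a binary incidence
matrix (1 = gene belongs to pathway).  Genes present in at least two
pathways are retained, and agglomerative clustering is run independently
on rows (genes sharing pathways) and columns (pathways sharing genes).

Distances on the binary vectors are Jaccard by default (Hamming
available).  Clustering is fully deterministic: cluster-pair distances
are computed with exact rational arithmetic (initial Jaccard/Hamming
distances are rationals and average linkage preserves rationality), and
ties in the minimal distance are broken by the lexicographically smallest
label pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from collections.abc import Mapping, Iterable

import numpy as np
import pandas as pd

DISTANCES = ("jaccard", "hamming")
LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True, eq=False)
class MembershipMatrix:
    """Ordered binary incidence of genes (rows) in pathways (columns)."""

    genes: tuple[str, ...]
    pathways: tuple[str, ...]
    values: np.ndarray  # shape (len(genes), len(pathways)), entries 0/1

    def __eq__(self, other) -> bool:
        if not isinstance(other, MembershipMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.pathways == other.pathways
            and np.array_equal(self.values, other.values)
        )

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.genes), len(self.pathways)):
            raise ValueError("matrix shape does not match labels")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("membership entries must be 0/1")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene row labels")
        if len(set(self.pathways)) != len(self.pathways):
            raise ValueError("duplicate pathway column labels")

    @property
    def row_sums(self) -> dict[str, int]:
        return dict(zip(self.genes, self.values.sum(axis=1).tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.genes), columns=list(self.pathways)
        )

    def transpose(self) -> "MembershipMatrix":
        return MembershipMatrix(
            genes=self.pathways, pathways=self.genes, values=self.values.T
        )


def build_matrix(
    pathway_gene_lists: Mapping[str, Iterable[str]],
    universe: set[str] | None = None,
) -> MembershipMatrix:
    """Incidence matrix over universe ∩ (union of pathway lists).

    Rows and columns are ordered lexicographically.  Genes in the universe
    that belong to no pathway are excluded (they would be all-zero rows,
    undefined under Jaccard distance).
    """
    if not pathway_gene_lists:
        raise ValueError("no pathway gene lists supplied")
    sets = {
        str(pid): {str(g).strip().upper() for g in genes}
        for pid, genes in pathway_gene_lists.items()
    }
    union = set().union(*sets.values())
    genes = union if universe is None else union & {
        str(g).strip().upper() for g in universe
    }
    gene_order = tuple(sorted(genes))
    path_order = tuple(sorted(sets))
    values = np.array(
        [[1 if g in sets[p] else 0 for p in path_order] for g in gene_order],
        dtype=np.int8,
    ).reshape(len(gene_order), len(path_order))
    return MembershipMatrix(genes=gene_order, pathways=path_order, values=values)


def filter_min_pathways(
    matrix: MembershipMatrix, min_pathways: int = 2
) -> MembershipMatrix:
    """Retain genes (rows) present in at least ``min_pathways`` pathways."""
    if min_pathways < 0:
        raise ValueError("min_pathways must be >= 0")
    keep = matrix.values.sum(axis=1) >= min_pathways
    return MembershipMatrix(
        genes=tuple(g for g, k in zip(matrix.genes, keep) if k),
        pathways=matrix.pathways,
        values=matrix.values[keep],
    )


# ---------------------------------------------------------------------------
# agglomerative clustering with exact arithmetic and lexicographic ties
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterTree:
    """Merge sequence of one clustering axis.

    Each merge is (left label set, right label set, height); heights are
    non-decreasing.  The left member is the cluster whose smallest leaf
    label is lexicographically smaller.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[frozenset, frozenset, float], ...]

    def leaf_order(self) -> list[str]:
        """Dendrogram leaf order (left subtree before right, recursively)."""
        order: dict[frozenset, list[str]] = {
            frozenset({leaf}): [leaf] for leaf in self.leaves
        }
        merged = None
        for left, right, _ in self.merges:
            merged = left | right
            order[merged] = order[left] + order[right]
        if merged is None:  # single leaf, no merges
            return list(self.leaves)
        return order[merged]

    def cut(self, k: int) -> list[set[str]]:
        """Partition into k clusters by undoing the k-1 highest merges."""
        if not 1 <= k <= len(self.leaves):
            raise ValueError(f"k={k} outside [1, {len(self.leaves)}]")
        clusters = {frozenset({leaf}) for leaf in self.leaves}
        for left, right, _ in self.merges[: len(self.merges) - (k - 1)]:
            clusters.discard(left)
            clusters.discard(right)
            clusters.add(left | right)
        return sorted((set(c) for c in clusters), key=lambda c: min(c))

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        height: dict[frozenset, float] = {
            frozenset({leaf}): 0.0 for leaf in self.leaves
        }
        text: dict[frozenset, str] = {
            frozenset({leaf}): leaf for leaf in self.leaves
        }
        root = frozenset(self.leaves)
        for left, right, h in self.merges:
            node = left | right
            parts = ",".join(
                f"{text[c]}:{h - height[c]:g}" for c in (left, right)
            )
            text[node] = f"({parts})"
            height[node] = h
        return text.get(root, text[frozenset({self.leaves[0]})]) + ";"


def _pairwise_exact(
    labels: list[str], vectors: np.ndarray, distance: str
) -> dict[frozenset, Fraction]:
    vectors = np.asarray(vectors, dtype=bool)
    dist: dict[frozenset, Fraction] = {}
    for i, a in enumerate(labels):
        if distance == "jaccard" and not vectors[i].any():
            raise ValueError(
                f"all-zero vector for {a!r}: Jaccard distance undefined; "
                f"pre-filter zero rows/columns (filter_min_pathways)"
            )
        for j in range(i + 1, len(labels)):
            b = labels[j]
            u, v = vectors[i], vectors[j]
            if distance == "jaccard":
                union = int((u | v).sum())
                inter = int((u & v).sum())
                dist[frozenset({a, b})] = Fraction(union - inter, union)
            else:  # hamming
                dist[frozenset({a, b})] = Fraction(int((u != v).sum()), len(u))
    return dist


def _cluster_distance(
    a: frozenset, b: frozenset, leaf_dist: dict[frozenset, Fraction],
    linkage: str,
) -> Fraction:
    pairs = [leaf_dist[frozenset({x, y})] for x in a for y in b]
    if linkage == "average":
        return sum(pairs, Fraction(0)) / len(pairs)
    if linkage == "complete":
        return max(pairs)
    return min(pairs)


def agglomerate(
    labels: list[str], vectors: np.ndarray,
    distance: str = "jaccard", linkage: str = "average",
) -> ClusterTree:
    """Deterministic agglomerative clustering of labelled binary vectors.

    Cluster distances are recomputed exactly from the leaf-level rational
    distances at every step (average/complete/single over member pairs);
    the minimal-distance pair is merged, ties resolved by the smallest
    (min-leaf-label, min-leaf-label) pair.
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels")
    if len(labels) < 2:
        return ClusterTree(leaves=tuple(labels), merges=())

    leaf_dist = _pairwise_exact(list(labels), vectors, distance)
    active: list[frozenset] = [frozenset({l}) for l in labels]
    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(active) > 1:
        best: tuple[Fraction, tuple[str, str]] | None = None
        best_pair: tuple[frozenset, frozenset] | None = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                d = _cluster_distance(a, b, leaf_dist, linkage)
                key_pair = tuple(sorted((min(a), min(b))))
                cand = (d, key_pair)
                if best is None or cand < best:
                    best = cand
                    best_pair = (a, b) if min(a) < min(b) else (b, a)
        assert best is not None and best_pair is not None
        left, right = best_pair
        merges.append((left, right, float(best[0])))
        active = [c for c in active if c is not left and c is not right]
        active.append(left | right)
    return ClusterTree(leaves=tuple(labels), merges=tuple(merges))


def bicluster(
    matrix: MembershipMatrix,
    distance: str = "jaccard",
    linkage: str = "average",
) -> tuple[ClusterTree, ClusterTree, MembershipMatrix]:
    """Cluster rows and columns independently; return both trees and the
    matrix reordered to the dendrogram leaf orders."""
    if len(matrix.genes) < 2 or len(matrix.pathways) < 2:
        raise ValueError("bi-clustering needs >= 2 rows and >= 2 columns")
    row_tree = agglomerate(
        list(matrix.genes), matrix.values, distance, linkage
    )
    col_tree = agglomerate(
        list(matrix.pathways), matrix.values.T, distance, linkage
    )
    row_order = row_tree.leaf_order()
    col_order = col_tree.leaf_order()
    frame = matrix.to_frame().loc[row_order, col_order]
    reordered = MembershipMatrix(
        genes=tuple(row_order),
        pathways=tuple(col_order),
        values=frame.to_numpy(dtype=np.int8),
    )
    return row_tree, col_tree, reordered


def cut_clusters(tree: ClusterTree, k: int) -> list[set[str]]:
    return tree.cut(k)


def write_matrix(matrix: MembershipMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_matrix(path) -> MembershipMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return MembershipMatrix(
        genes=tuple(str(g) for g in frame.index),
        pathways=tuple(str(p) for p in frame.columns),
        values=frame.to_numpy(dtype=np.int8),
    )
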