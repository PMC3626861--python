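"""Protein-protein interaction networks: fusion, neighborhoods, filtering.

The analysis works on one simple undirected graph over normalized gene
symbols, obtained by taking the union of several published edge lists
("network fusion").  Edge confidence scores (STRING-style, in [0, 1]) and
source tags are carried as metadata; the guilt-by-association prediction
step ignores scores, while the visualization-oriented subnetwork step can
filter on them.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


class InteractionNetwork:
    """Simple undirected interaction graph with per-edge score and sources.

    Thin wrapper over :class:`networkx.Graph`; node identity is the
    normalized (uppercased, stripped) gene symbol.  Invariants: no
    self-loops, no parallel edges, scores in [0, 1] when present.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def edges(self):
        """Iterate (gene_a, gene_b, score, sources) with a <= b."""
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            yield a, b, data.get("score"), frozenset(data.get("sources", ()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and set(
            (a, b) for a, b, _, _ in self.edges()
        ) == set((a, b) for a, b, _, _ in other.edges())

    def __repr__(self) -> str:
        return f"InteractionNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


def _normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def read_edge_list(path) -> pd.DataFrame:
    """Read an edge-list TSV with columns gene_a, gene_b[, score][, source]."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    if not {"gene_a", "gene_b"}.issubset(table.columns):
        raise ValueError(f"edge list {path} lacks gene_a/gene_b columns")
    return table


def fuse_networks(
    edge_tables: Iterable[pd.DataFrame],
    source_names: Iterable[str] | None = None,
) -> InteractionNetwork:
    """Union several edge-list tables into one simple undirected network.

    An edge present in k source tables carries the union of their source
    tags and the maximum of their scores; self-loops are dropped with a
    logged count.  Raises if the fused network would be empty.
    """
    tables = list(edge_tables)
    names = list(source_names) if source_names is not None else [
        str(t.attrs.get("source", f"source_{i}")) for i, t in enumerate(tables)
    ]
    graph = nx.Graph()
    n_self_loops = 0
    for table, default_source in zip(tables, names):
        has_score = "score" in table.columns
        has_source = "source" in table.columns
        for row in table.itertuples(index=False):
            a = _normalize_symbol(row.gene_a)
            b = _normalize_symbol(row.gene_b)
            if not a or not b:
                raise ValueError("edge with empty gene symbol")
            if a == b:
                n_self_loops += 1
                continue
            score = None
            if has_score and pd.notna(row.score):
                score = float(row.score)
                if not 0.0 <= score <= 1.0:
                    raise ValueError(f"edge {a}-{b}: score {score} outside [0,1]")
            source = (
                str(row.source) if has_source and pd.notna(row.source)
                else default_source
            )
            if graph.has_edge(a, b):
                data = graph[a][b]
                data["sources"] = data["sources"] | {source}
                old = data.get("score")
                if score is not None:
                    data["score"] = score if old is None else max(old, score)
            else:
                graph.add_edge(a, b, score=score, sources=frozenset({source}))
    if n_self_loops:
        logger.warning("dropped %d self-loop edges during fusion", n_self_loops)
    if graph.number_of_edges() == 0:
        raise ValueError("network fusion produced no edges")
    return InteractionNetwork(graph)


def first_neighbor_background(net: InteractionNetwork, seed: set[str]) -> set[str]:
    """Seed genes plus every node adjacent to a seed node.

    This is the custom enrichment background: the candidate cohort together
    with its first neighbors in the interaction network.  Seed genes absent
    from the network contribute themselves only (logged).
    """
    seed = {_normalize_symbol(g) for g in seed}
    missing = seed - net.nodes
    if missing:
        logger.warning(
            "%d seed genes absent from the network: %s",
            len(missing), ", ".join(sorted(missing)[:10]),
        )
    background = set(seed)
    for gene in seed & net.nodes:
        background |= net.neighbors(gene)
    return background


def filter_high_confidence(
    net: InteractionNetwork, min_score: float = 0.7
) -> InteractionNetwork:
    """Keep edges with score >= min_score; unscored edges are dropped.

    Mirrors STRING's "high confidence" filtering (conventional cutoff 0.7).
    Isolated nodes are removed from the result.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must be in [0, 1]")
    graph = nx.Graph()
    n_unscored = 0
    for a, b, score, sources in net.edges():
        if score is None:
            n_unscored += 1
            continue
        if score >= min_score:
            graph.add_edge(a, b, score=score, sources=sources)
    if n_unscored:
        logger.info("dropped %d unscored edges in confidence filter", n_unscored)
    return InteractionNetwork(graph)


def subnetwork(net: InteractionNetwork, genes: set[str]) -> InteractionNetwork:
    """Induced subgraph on genes ∩ nodes (isolated members retained as nodes)."""
    genes = {_normalize_symbol(g) for g in genes}
    sub = net.graph.subgraph(genes & net.nodes).copy()
    return InteractionNetwork(sub)


def interaction_report(net: InteractionNetwork, genes: set[str]) -> dict[str, bool]:
    """Per input gene, whether it retains >= 1 interaction in the induced subgraph."""
    sub = subnetwork(net, genes)
    return {
        _normalize_symbol(g): sub.graph.degree(_normalize_symbol(g)) > 0
        if _normalize_symbol(g) in sub.nodes
        else False
        for g in genes
    }


def write_network(net: InteractionNetwork, path, report_path=None) -> None:
    """Write the edge-list TSV dialect plus an optional JSON summary report."""
    rows = []
    per_source: dict[str, int] = {}
    for a, b, score, sources in sorted(net.edges()):
        rows.append(
            (a, b, "" if score is None else score, ",".join(sorted(sources)))
        )
        for s in sources:
            per_source[s] = per_source.get(s, 0) + 1
    frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "source"])
    frame.to_csv(path, sep="\t", index=False)
    if report_path is not None:
        report = {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "edges_per_source": per_source,
        }
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
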