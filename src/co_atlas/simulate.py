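"""Synthetic networks, cohorts, planted candidates and pathway annotations.

The generator emulates the statistical structure the analysis assumes: an
undirected simple background network (Erdős–Rényi, or a configuration
model with truncated power-law degrees for a more PPIN-like heavy tail),
a seed cohort of "known" candidate genes, a set of planted non-seed genes
rewired to concentrate edges into the cohort (the guilt-by-association
signal), and pathway gene sets in which designated "enriched" pathways
draw a fixed fraction of members from cohort ∪ planted genes.

Planting rewires rather than inflates: where a planted gene has spare
non-cohort edges they are swapped into the cohort, preserving its total
degree, so the signal is connectivity concentration and the
hypergeometric neighborhood test is the matched detector.

All generators are deterministic functions of ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import Pathway
from .network import InteractionNetwork


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one synthetic dataset.

    Defaults are the strong-signal configuration used throughout the test
    suite: 2000 genes, ER edge density 0.005 (mean degree ~10), a
    50-gene cohort, 20 planted candidates with 12 cohort edges each, and
    20 pathways of which 5 are enriched at 50% cohort/planted membership.
    """

    n_nodes: int = 2000
    edge_model: str = "erdos_renyi"  # or "configuration"
    er_p: float = 0.005
    degree_exponent: float = 2.5
    seed_cohort_size: int = 50
    n_planted: int = 20
    planted_seed_edges: int = 12
    n_pathways: int = 20
    n_enriched: int = 5
    pathway_size_range: tuple[int, int] = (10, 30)
    planted_pathway_overlap: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_model not in ("erdos_renyi", "configuration"):
            raise ValueError(f"unknown edge model {self.edge_model!r}")
        if self.seed_cohort_size + self.n_planted > self.n_nodes:
            raise ValueError("cohort + planted genes exceed node count")
        if self.planted_seed_edges > self.seed_cohort_size:
            raise ValueError(
                "planted_seed_edges cannot exceed the cohort size "
                "(planted genes need that many distinct cohort neighbors)"
            )
        if not 0.0 <= self.planted_pathway_overlap <= 1.0:
            raise ValueError("planted_pathway_overlap must be in [0,1]")
        if not 0.0 <= self.er_p <= 1.0:
            raise ValueError("er_p must be in [0,1]")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid pathway_size_range")
        if self.n_enriched > self.n_pathways:
            raise ValueError("n_enriched exceeds n_pathways")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _background_graph(config: SimulationConfig, rng: np.random.Generator) -> nx.Graph:
    n = config.n_nodes
    if config.edge_model == "erdos_renyi":
        graph_seed = int(rng.integers(2**31))
        return nx.fast_gnp_random_graph(n, config.er_p, seed=graph_seed)
    # configuration model, truncated power-law degree sequence
    kmax = max(2, int(np.sqrt(n)))
    ks = np.arange(1, kmax + 1)
    weights = ks.astype(float) ** (-config.degree_exponent)
    weights /= weights.sum()
    degrees = rng.choice(ks, size=n, p=weights)
    if degrees.sum() % 2:
        degrees[int(rng.integers(n))] += 1
    graph_seed = int(rng.integers(2**31))
    multi = nx.configuration_model(degrees.tolist(), seed=graph_seed)
    graph = nx.Graph(multi)  # collapse parallel edges
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


def generate_network(
    config: SimulationConfig,
) -> tuple[InteractionNetwork, set[str], set[str], pd.DataFrame]:
    """Background network + cohort + planted genes + truth table.

    Each planted gene ends with >= config.planted_seed_edges distinct
    cohort neighbors; rewiring swaps its non-cohort edges into the cohort
    where possible (degree-preserving) and adds fresh cohort edges only
    when the gene has no spare edges left.  The truth table has one row
    per planted gene.
    """
    rng = np.random.default_rng(config.rng_seed)
    graph = _background_graph(config, rng)
    names = _gene_names(config.n_nodes)
    graph = nx.relabel_nodes(graph, dict(enumerate(names)))
    graph.add_nodes_from(names)  # keep isolated nodes in the universe

    picks = rng.choice(
        config.n_nodes, size=config.seed_cohort_size + config.n_planted,
        replace=False,
    )
    cohort = {names[i] for i in picks[: config.seed_cohort_size]}
    planted = {names[i] for i in picks[config.seed_cohort_size:]}

    for gene in sorted(planted):
        current = set(graph.neighbors(gene)) & cohort
        deficit = config.planted_seed_edges - len(current)
        if deficit <= 0:
            continue
        eligible = sorted(cohort - current - {gene})
        if len(eligible) < deficit:
            raise ValueError(f"cannot wire {gene} to {deficit} more cohort genes")
        new_neighbors = rng.choice(eligible, size=deficit, replace=False)
        removable = sorted(
            set(graph.neighbors(gene)) - cohort - planted
        )
        rng.shuffle(removable)
        for target in new_neighbors:
            if removable:
                graph.remove_edge(gene, removable.pop())
            graph.add_edge(gene, target)

    for u, v in graph.edges:
        graph[u][v].setdefault("score", None)
        graph[u][v].setdefault("sources", frozenset({"synthetic"}))

    truth = pd.DataFrame(
        [
            (g, len(set(graph.neighbors(g)) & cohort))
            for g in sorted(planted)
        ],
        columns=["gene", "cohort_edges"],
    )
    return InteractionNetwork(graph), cohort, planted, truth


def generate_pathways(
    config: SimulationConfig,
    cohort: set[str],
    planted: set[str],
    universe: set[str],
) -> tuple[list[Pathway], dict[str, bool]]:
    """Pathway gene sets with planted over-representation.

    The first ``config.n_enriched`` pathways draw
    ``planted_pathway_overlap`` of their members from cohort ∪ planted
    (clamped to the pool size) and the rest uniformly from the remaining
    universe; null pathways are uniform draws from the whole universe.
    Returns the collection plus an {id: enriched} truth map.
    """
    rng = np.random.default_rng([config.rng_seed, 1])
    universe_sorted = sorted(universe)
    pool = sorted((set(cohort) | set(planted)) & universe)
    lo, hi = config.pathway_size_range
    if hi > len(universe_sorted):
        raise ValueError("pathway size range exceeds universe size")

    pathways: list[Pathway] = []
    truth: dict[str, bool] = {}
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        enriched = i < config.n_enriched
        name = f"PW{i:03d}"
        if enriched:
            n_signal = min(round(config.planted_pathway_overlap * size), len(pool))
            signal = set(rng.choice(pool, size=n_signal, replace=False)) if n_signal else set()
            rest_pool = sorted(set(universe_sorted) - signal)
            rest = set(rng.choice(rest_pool, size=size - n_signal, replace=False))
            members = signal | rest
        else:
            members = set(rng.choice(universe_sorted, size=size, replace=False))
        pathways.append(
            Pathway(
                id=name,
                source_db="SYNTH",
                members=frozenset(members),
                description="enriched" if enriched else "null",
            )
        )
        truth[name] = enriched
    return pathways, truth


def permute_seed_labels(
    net: InteractionNetwork, seed_size: int, rng_seed: int
) -> set[str]:
    """Uniform random node subset of the given size (permutation null)."""
    nodes = sorted(net.nodes)
    if seed_size > len(nodes):
        raise ValueError("seed_size exceeds node count")
    rng = np.random.default_rng(rng_seed)
    return set(rng.choice(nodes, size=seed_size, replace=False))


def write_simulation(
    out_dir,
    config: SimulationConfig,
    net: InteractionNetwork,
    cohort: set[str],
    planted: set[str],
    truth: pd.DataFrame,
    pathways: list[Pathway] | None = None,
) -> None:
    """Write edges.tsv, seed.txt, truth.tsv, pathways.gmt and a config echo."""
    from pathlib import Path

    from .io import write_gene_list, write_gmt
    from .network import write_network

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_network(net, out / "edges.tsv", out / "network_report.json")
    write_gene_list(cohort, out / "seed.txt", header="synthetic seed cohort")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    if pathways is not None:
        write_gmt(pathways, out / "pathways.gmt")
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
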