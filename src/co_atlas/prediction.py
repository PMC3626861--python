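"""Guilt-by-association candidate prediction on an interaction network.

Given a seed cohort of known candidate genes, every non-seed first
neighbor g is tested for whether its connectivity into the cohort exceeds
chance: with N = |nodes| - 1 possible interaction partners, K seed genes
in the network and degree n_g, the count k_g of g's edges into the seed
follows Hypergeometric(N, K, n_g) under random wiring, and the upper tail
P(X >= k_g) is Bonferroni-corrected over the tested first neighbors.
Genes significant at alpha (default 0.01) are the network-predicted
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .enrichment import bonferroni
from .network import InteractionNetwork


@dataclass(frozen=True)
class PredictionResult:
    gene: str
    degree: int
    seed_edges: int
    N: int
    K: int
    p_raw: float
    p_adj: float
    predicted: bool


class PredictedSet(NamedTuple):
    genes: set[str]
    max_p_adj: float | None


def predict_candidates(
    net: InteractionNetwork, seed: set[str], alpha: float = 0.01
) -> list[PredictionResult]:
    """Test every non-seed first neighbor of the seed cohort.

    Returns results sorted by ascending adjusted p then gene symbol; the
    Bonferroni family size is the number of tested first neighbors.  The
    universe size N and seed count K are emitted per gene for audit.
    Raises if the seed is disjoint from the network.
    """
    seed = {str(g).strip().upper() for g in seed}
    seed_in_net = seed & net.nodes
    if not seed_in_net:
        raise ValueError("seed cohort is disjoint from the network")

    candidates = sorted(
        {nb for s in seed_in_net for nb in net.neighbors(s)} - seed
    )
    if not candidates:
        return []

    N = net.n_nodes - 1
    K = len(seed_in_net)
    degrees = np.array([net.degree(g) for g in candidates])
    seed_edges = np.array(
        [len(net.neighbors(g) & seed_in_net) for g in candidates]
    )
    p_raw = hypergeom.sf(seed_edges - 1, N, K, degrees)
    p_adj = bonferroni(list(p_raw))

    results = [
        PredictionResult(
            gene=g,
            degree=int(d),
            seed_edges=int(k),
            N=N,
            K=K,
            p_raw=float(p),
            p_adj=float(pa),
            predicted=pa <= alpha,
        )
        for g, d, k, p, pa in zip(candidates, degrees, seed_edges, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.gene))
    return results


def predicted_set(results: list[PredictionResult]) -> PredictedSet:
    """Significant genes plus the largest adjusted p among them (the
    published-style "Bonferroni p < x" bound); max_p_adj is None when no
    gene is predicted."""
    genes = {r.gene for r in results if r.predicted}
    max_p = max((r.p_adj for r in results if r.predicted), default=None)
    return PredictedSet(genes=genes, max_p_adj=max_p)


def write_predictions(results: list[PredictionResult], path) -> None:
    frame = pd.DataFrame(
        [
            (r.gene, r.degree, r.seed_edges, r.N, r.K, r.p_raw, r.p_adj,
             int(r.predicted))
            for r in results
        ],
        columns=[
            "gene", "degree", "seed_edges", "N", "K", "p_raw", "p_adj",
            "predicted",
        ],
    )
    frame.to_csv(path, sep="\t", index=False)
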