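"""Hypergeometric over-representation analysis against a custom background.

A query gene set (the candidate cohort) is tested for over-representation
in each pathway gene set relative to an explicit background universe —
here the cohort plus its first neighbors in the interaction network, not
the whole genome.  For a pathway with K members in the background of size
N and a query of size n overlapping it in k genes, the raw p-value is the
upper tail P(X >= k) of X ~ Hypergeometric(N, K, n).  Bonferroni
correction multiplies by the number of testable pathways (those with at
least one background member) and significance is called at p_adj <= alpha
(default 0.01).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pathway:
    """A named gene set from a pathway database (KEGG, REACTOME, ...)."""

    id: str
    source_db: str = ""
    members: frozenset = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.id!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    source_db: str
    overlap_genes: frozenset
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts pathway members in a draw of n genes without replacement from
    a background of N genes of which K are pathway members.  Arguments are
    validated against 0 <= k <= n <= N, 0 <= K <= N and k <= K.
    """
    if not 0 <= k:
        raise ValueError(f"k={k} violates 0 <= k")
    if not k <= n:
        raise ValueError(f"k={k}, n={n} violates k <= n")
    if not n <= N:
        raise ValueError(f"n={n}, N={N} violates n <= N")
    if not 0 <= K <= N:
        raise ValueError(f"K={K}, N={N} violates 0 <= K <= N")
    if not k <= K:
        raise ValueError(f"k={k}, K={K} violates k <= K")
    if k == 0:
        return 1.0  # also covers the degenerate empty universe
    # sf(k-1) = P(X >= k); exact to ~1e-15 relative for N <= 1e4
    return float(hypergeom.sf(k - 1, N, K, n))


def bonferroni(p_values: list[float]) -> list[float]:
    """Family-wise correction: each p becomes min(1, m*p), m = list length."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


def enrich(
    query: set[str],
    pathways: list[Pathway],
    background: set[str],
    alpha: float = 0.01,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each pathway given ``background``.

    Genes outside the background are dropped from the query and from each
    pathway (with a warning); pathways left without background members are
    untestable and excluded from the Bonferroni family.  ``ease=True``
    switches to the EASE-conservative variant that subtracts one from the
    observed overlap.  Results are sorted by ascending adjusted p, ties by
    pathway id.
    """
    if not background:
        raise ValueError("empty enrichment background")
    background = {g.strip().upper() for g in background}
    query = {g.strip().upper() for g in query}
    outside = query - background
    if outside:
        logger.warning(
            "%d query genes outside the background were dropped", len(outside)
        )
    query &= background
    if not query:
        logger.warning("query empty after background intersection")
        return []

    N = len(background)
    n = len(query)
    testable: list[tuple[Pathway, frozenset, int]] = []
    for pw in pathways:
        members = frozenset(g for g in pw.members if g in background)
        if members:
            testable.append((pw, members, len(members)))
        else:
            logger.info("pathway %s has no background members; skipped", pw.id)

    raw: list[float] = []
    rows: list[tuple[Pathway, frozenset, int, int]] = []
    for pw, members, K in testable:
        overlap = frozenset(query & members)
        k = len(overlap)
        k_eff = max(k - 1, 0) if ease else k
        raw.append(hypergeom_tail(k_eff, K, n, N))
        rows.append((pw, overlap, k, K))
    adjusted = bonferroni(raw)

    results = [
        EnrichmentResult(
            pathway_id=pw.id,
            source_db=pw.source_db,
            overlap_genes=overlap,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p,
            p_adj=p_adj,
            significant=p_adj <= alpha,
        )
        for (pw, overlap, k, K), p, p_adj in zip(rows, raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adj, r.pathway_id))
    return results


def write_results(
    results: list[EnrichmentResult], path, report_path=None, alpha: float = 0.01
) -> None:
    frame = pd.DataFrame(
        [
            (
                r.pathway_id, r.source_db, r.k, r.K, r.n, r.N, r.p_raw,
                r.p_adj, int(r.significant), ",".join(sorted(r.overlap_genes)),
            )
            for r in results
        ],
        columns=[
            "pathway", "source_db", "k", "K", "n", "N", "p_raw", "p_adj",
            "significant", "overlap_genes",
        ],
    )
    frame.to_csv(path, sep="\t", index=False)
    if report_path is not None:
        report = {
            "alpha": alpha,
            "n_tests": len(results),
            "background_size": results[0].N if results else 0,
            "n_significant": sum(r.significant for r in results),
        }
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
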