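"""Three-criterion candidate prioritization.

Candidates are ranked by (1) the number of independent literature reports,
(2) participation in significantly enriched pathways (row sum in the
binary membership matrix), and (3) positional overlap with a chromosomal
aberration region.  No weighting formula is imposed: genes are ordered by
how many criteria they meet, then by the individual criterion values, then
lexicographically, and the full sort key is emitted so users can re-rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .biclustering import MembershipMatrix
from .evidence import EvidenceSummary


@dataclass(frozen=True)
class PriorityRecord:
    gene: str
    n_reports: int
    n_pathways: int
    positional: bool
    criteria_met: int
    rank: int


def pathway_participation(
    matrix: MembershipMatrix, min_pathways: int
) -> set[str]:
    """Genes present in at least ``min_pathways`` of the matrix's pathways."""
    if min_pathways < 1:
        raise ValueError("min_pathways must be >= 1")
    return {g for g, s in matrix.row_sums.items() if s >= min_pathways}


def rank_candidates(
    evidence: list[EvidenceSummary],
    matrix: MembershipMatrix,
    positional: set[str],
    min_reports: int = 2,
) -> list[PriorityRecord]:
    """Deterministic ranking over the union of the three gene universes.

    criteria_met = [n_reports >= min_reports] + [n_pathways >= 1] +
    [positional]; sort key is (criteria_met, n_reports, n_pathways,
    positional) descending, ties by gene symbol.  Genes absent from a
    source score 0/False there.
    """
    reports = {s.gene: s.report_count for s in evidence}
    pathways = matrix.row_sums
    positional = {str(g).strip().upper() for g in positional}
    universe = set(reports) | set(pathways) | positional

    scored = []
    for gene in universe:
        n_rep = reports.get(gene, 0)
        n_pw = pathways.get(gene, 0)
        pos = gene in positional
        met = int(n_rep >= min_reports) + int(n_pw >= 1) + int(pos)
        scored.append((gene, n_rep, n_pw, pos, met))
    scored.sort(key=lambda t: (-t[4], -t[1], -t[2], -int(t[3]), t[0]))
    return [
        PriorityRecord(
            gene=g, n_reports=r, n_pathways=p, positional=pos,
            criteria_met=met, rank=i + 1,
        )
        for i, (g, r, p, pos, met) in enumerate(scored)
    ]


def write_ranking(records: list[PriorityRecord], path) -> None:
    pd.DataFrame(
        [
            (r.rank, r.gene, r.criteria_met, r.n_reports, r.n_pathways,
             int(r.positional))
            for r in records
        ],
        columns=["rank", "gene", "criteria_met", "n_reports", "n_pathways",
                 "positional"],
    ).to_csv(path, sep="\t", index=False)
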