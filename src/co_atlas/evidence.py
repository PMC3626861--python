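"""Curated literature-evidence table: loading, validation and report counting.

Candidate genes for cryptorchidism are collected from heterogeneous study
approaches (chromosomal aberrations, CNVs, clinical syndromes, knock-out and
transgenic models, association studies, expression profiling, protein-level
experiments) across several mammalian species.  A gene's credibility grows
with the number of *independent reports* backing it; here a report is a
distinct (approach, species, reference) triple, so five human association
studies count five times while a re-listing of the same study counts once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: The seven study approaches under which evidence is curated.
APPROACHES = frozenset(
    {
        "chromosomal_aberration",
        "cnv",
        "syndrome",
        "knockout_transgenic",
        "association",
        "expression",
        "protein",
    }
)

_COLUMNS = ["gene", "approach", "species", "reference"]


@dataclass(frozen=True, order=True)
class EvidenceRecord:
    """One independent literature report linking a gene to the phenotype."""

    gene: str
    approach: str
    species: str
    reference: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("evidence record with empty gene symbol")
        if self.approach not in APPROACHES:
            raise ValueError(
                f"unknown approach {self.approach!r} for gene {self.gene!r}; "
                f"expected one of {sorted(APPROACHES)}"
            )


@dataclass(frozen=True)
class EvidenceSummary:
    """Per-gene tally of independent reports (prioritization criterion 1)."""

    gene: str
    report_count: int
    approaches: frozenset = field(default_factory=frozenset)
    multi_evidence: bool = False


def _normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def load_evidence(path) -> list[EvidenceRecord]:
    """Read a four-column evidence TSV, validating and de-duplicating rows.

    The file must have a header naming ``gene``, ``approach``, ``species``
    and ``reference``; ``#``-prefixed lines are ignored.  Gene symbols are
    uppercased and whitespace-stripped.  Exact duplicate rows are dropped
    with a log message.  An unknown approach or an empty gene symbol is a
    hard error naming the offending row.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"evidence table {path} lacks columns {missing}")

    records: list[EvidenceRecord] = []
    seen: set[EvidenceRecord] = set()
    n_dupes = 0
    for idx, row in table.iterrows():
        gene = _normalize_symbol(row["gene"]) if pd.notna(row["gene"]) else ""
        try:
            rec = EvidenceRecord(
                gene=gene,
                approach=str(row["approach"]).strip(),
                species=str(row["species"]).strip(),
                reference=str(row["reference"]).strip(),
            )
        except ValueError as exc:
            # pandas rows are 0-based and exclude the header line
            raise ValueError(f"row {idx + 2} of {path}: {exc}") from exc
        if rec in seen:
            n_dupes += 1
            continue
        seen.add(rec)
        records.append(rec)
    if n_dupes:
        logger.info("dropped %d duplicate evidence rows from %s", n_dupes, path)
    return records


def write_evidence(records: list[EvidenceRecord], path) -> None:
    """Write records back to the four-column TSV dialect read by load_evidence."""
    frame = pd.DataFrame(
        [(r.gene, r.approach, r.species, r.reference) for r in records],
        columns=_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def count_reports(
    records: list[EvidenceRecord], min_reports: int = 2
) -> list[EvidenceSummary]:
    """Tally distinct reports per gene.

    Returns one summary per distinct gene, ordered by descending report
    count then lexicographic gene symbol.  ``multi_evidence`` flags genes
    meeting the ``min_reports`` threshold.
    """
    by_gene: dict[str, set[EvidenceRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, set()).add(rec)
    summaries = [
        EvidenceSummary(
            gene=gene,
            report_count=len(recs),
            approaches=frozenset(r.approach for r in recs),
            multi_evidence=len(recs) >= min_reports,
        )
        for gene, recs in by_gene.items()
    ]
    summaries.sort(key=lambda s: (-s.report_count, s.gene))
    return summaries


def multi_evidence_genes(
    summaries: list[EvidenceSummary], min_reports: int = 2
) -> set[str]:
    """Genes backed by at least ``min_reports`` independent reports."""
    if min_reports < 1:
        raise ValueError("min_reports must be >= 1")
    return {s.gene for s in summaries if s.report_count >= min_reports}


def write_summary(summaries: list[EvidenceSummary], path) -> None:
    frame = pd.DataFrame(
        [
            (s.gene, s.report_count, ",".join(sorted(s.approaches)),
             int(s.multi_evidence))
            for s in summaries
        ],
        columns=["gene", "report_count", "approaches", "multi_evidence"],
    )
    frame.to_csv(path, sep="\t", index=False)
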