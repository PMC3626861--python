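"""Rank candidate genes by the three prioritization criteria.

Combines independent-report counts, enriched-pathway participation (row
sums in the significant-pathway membership matrix) and positional-overlap
status into a deterministic ranked list.
"""

from pathlib import Path

from co_atlas import biclustering as bc
from co_atlas import evidence as ev
from co_atlas import fixtures
from co_atlas import positional as pos
from co_atlas import prioritization as prio

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summaries = ev.count_reports(fixtures.table2_evidence_records())
    matrix = bc.build_matrix(
        fixtures.pathway_gene_lists(fixtures.table4_pathways()),
        fixtures.combined_cohort(),
    )
    positional = pos.positional_candidates(
        fixtures.literature_gene_intervals(), fixtures.aberration_intervals()
    ) | pos.positional_candidates(
        fixtures.network_gene_intervals(), fixtures.aberration_intervals()
    )

    ranking = prio.rank_candidates(summaries, matrix, positional)
    OUT.mkdir(parents=True, exist_ok=True)
    prio.write_ranking(ranking, OUT / "prioritization.tsv")

    print(f"{len(ranking)} genes ranked; top 5:")
    for r in ranking[:5]:
        print(
            f"  {r.rank}. {r.gene}  criteria={r.criteria_met}/3  "
            f"reports={r.n_reports}  pathways={r.n_pathways}  "
            f"positional={'yes' if r.positional else 'no'}"
        )
    seven_plus = prio.pathway_participation(
        bc.build_matrix(
            fixtures.pathway_gene_lists(fixtures.table3_literature_pathways())
        ),
        7,
    )
    print(
        "genes in >= 7 literature-cohort pathways: "
        + ", ".join(sorted(seven_plus))
    )
    print(f"wrote {OUT / 'prioritization.tsv'}")


if __name__ == "__main__":
    main()
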