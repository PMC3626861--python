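"""Call positional candidates by gene / aberration interval overlap.

Intersects candidate-gene coordinates with chromosomal aberration and CNV
regions (representative fixture coordinates), reporting per-gene hits,
the 11p15.5 breakpoint trio, and aberration regions that overlap each
other.
"""

from pathlib import Path

from co_atlas import fixtures
from co_atlas import positional as pos

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lit_genes = fixtures.literature_gene_intervals()
    net_genes = fixtures.network_gene_intervals()
    aberrations = fixtures.aberration_intervals()

    OUT.mkdir(parents=True, exist_ok=True)
    pos.write_overlaps(lit_genes + net_genes, aberrations,
                       OUT / "positional_overlaps.tsv")

    lit_hits = pos.positional_candidates(lit_genes, aberrations)
    net_hits = pos.positional_candidates(net_genes, aberrations)
    print(
        f"{len(lit_hits)} literature and {len(net_hits)} network-predicted "
        f"positional candidates"
    )
    trio = pos.positional_candidates(
        lit_genes, [fixtures.breakpoint_11p15_interval()]
    )
    print(f"11p15.5 breakpoint overlaps: {', '.join(sorted(trio))}")
    for a, b in pos.aberration_pair_overlaps(aberrations):
        print(f"aberration regions overlapping each other: {a} ~ {b}")
    print(f"wrote {OUT / 'positional_overlaps.tsv'}")


if __name__ == "__main__":
    main()
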