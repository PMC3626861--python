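"""Positional candidate calling by genomic interval overlap.

Candidate genes whose coordinates intersect a chromosomal aberration or
CNV region are positional candidates.  Coordinates are BED convention
throughout: 0-based, half-open [start, end), so adjacent intervals do not
overlap; chromosome labels are compared after stripping any ``chr``
prefix; any 1-bp intersection counts (no reciprocal-fraction rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval with empty chromosome")
        if self.start < 0:
            raise ValueError(f"{self.label}: negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"{self.label}: start {self.start} >= end {self.end}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            _norm_chrom(self.chrom) == _norm_chrom(other.chrom)
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> tuple[int, int]:
        return max(self.start, other.start), min(self.end, other.end)


def _norm_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_bed(path) -> list[GenomicInterval]:
    """Parse a BED3+ file (chrom, start, end[, name]); hard error with the
    line number on malformed or inverted coordinates."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            label = fields[3] if len(fields) >= 4 else f"{fields[0]}:{start}-{end}"
            try:
                intervals.append(
                    GenomicInterval(
                        chrom=fields[0], start=start, end=end, label=label
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: list[GenomicInterval], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def overlap_candidates(
    genes: list[GenomicInterval], aberrations: list[GenomicInterval]
) -> dict[str, list[str]]:
    """Map each overlapping gene label to its aberration labels.

    A gene appearing in the result (>= 1 overlapping aberration) is a
    positional candidate.  Genes are keyed in (chrom, start) order and
    aberration labels listed in (chrom, start) order; genes without
    overlap are absent.
    """
    gene_order = sorted(genes, key=lambda g: (_norm_chrom(g.chrom), g.start, g.label))
    ab_order = sorted(
        aberrations, key=lambda a: (_norm_chrom(a.chrom), a.start, a.label)
    )
    out: dict[str, list[str]] = {}
    for g in gene_order:
        hits = [a.label for a in ab_order if g.overlaps(a)]
        if hits:
            out[g.label] = hits
    return out


def positional_candidates(
    genes: list[GenomicInterval], aberrations: list[GenomicInterval]
) -> set[str]:
    """Gene labels overlapping at least one aberration region."""
    return set(overlap_candidates(genes, aberrations))


def aberration_pair_overlaps(
    aberrations: list[GenomicInterval],
) -> list[tuple[str, str]]:
    """All unordered pairs of aberration regions that themselves overlap."""
    ordered = sorted(
        aberrations, key=lambda a: (_norm_chrom(a.chrom), a.start, a.label)
    )
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if a.overlaps(b):
                pairs.append(tuple(sorted((a.label, b.label))))
    return sorted(set(pairs))


def write_overlaps(
    genes: list[GenomicInterval],
    aberrations: list[GenomicInterval],
    path,
) -> None:
    by_label = {g.label: g for g in genes}
    ab_by_label = {a.label: a for a in aberrations}
    rows = []
    for gene, hits in overlap_candidates(genes, aberrations).items():
        for ab in hits:
            g, a = by_label[gene], ab_by_label[ab]
            lo, hi = g.intersection(a)
            rows.append((gene, ab, _norm_chrom(g.chrom), lo, hi))
    pd.DataFrame(
        rows, columns=["gene", "aberration", "chrom", "overlap_start", "overlap_end"]
    ).to_csv(path, sep="\t", index=False)
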