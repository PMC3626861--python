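"""Small text-format helpers: GMT gene sets and one-symbol-per-line lists.

The GMT dialect is the standard tab-separated one (set name, description,
then member genes).  Set names of the form ``SOURCE|Name`` split into a
source database tag and a pathway name; the description column is free
text and round-trips unchanged, which lets fixture files carry provenance
metadata (e.g. published Bonferroni p-values).
"""

from __future__ import annotations

from .enrichment import Pathway


def read_gmt(path) -> list[Pathway]:
    """Parse a GMT file into Pathway objects (comment lines start with #)."""
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 gene"
                )
            name, description = fields[0], fields[1]
            members = {g.strip().upper() for g in fields[2:] if g.strip()}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            source_db, _, bare = name.partition("|")
            if not bare:
                source_db, bare = "", name
            pathways.append(
                Pathway(
                    id=name, source_db=source_db, members=frozenset(members),
                    description=description,
                )
            )
    ids = [p.id for p in pathways]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate gene-set ids in {path}")
    return pathways


def write_gmt(pathways: list[Pathway], path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            genes = "\t".join(sorted(p.members))
            fh.write(f"{p.id}\t{p.description}\t{genes}\n")


def read_gene_list(path) -> set[str]:
    """One symbol per line, ``#`` comments ignored, symbols normalized."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.upper())
    return genes


def write_gene_list(genes: set[str], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in sorted(genes):
            fh.write(g + "\n")
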