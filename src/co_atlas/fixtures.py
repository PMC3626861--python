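"""Transcriptions of the published cryptorchidism candidate-gene tables.

The study's raw material is literature-curated: an evidence table of genes
backed by at least two independent reports (Table 2), pathway
over-representation results for the 179 literature-collected and the 43
network-predicted candidate cohorts (Table 3), the joint 222-gene analysis
(Table 4, 12 significant pathways), and positional-candidate findings
(aberration regions on chromosomes 2, 4, 8, 9, 10, 11 and X).  These are
packaged here as in-memory constants and as an emitted fixture bundle so
the whole pipeline can be exercised without any remote resource.

The published Bonferroni p-values depend on a 2012-era annotation corpus
and an unpublished fused interaction network; they are carried verbatim as
metadata, not recomputed.  Cytogenetic bands are published without base
pairs, so interval fixtures use representative coordinates; only the
set-identity of overlap calls is meaningful, never the raw numbers.  The
full 179/43 cohort rosters live in unpublished supplementary files: the
rosters here contain every symbol printed in the main text, padded to the
stated sizes with clearly labelled synthetic placeholders (``SYNLIT###``/
``SYNNET##``) so that whole-cohort counts (179 + 43 = 222 unique genes)
are exercisable.
"""

from __future__ import annotations

from pathlib import Path

from .enrichment import Pathway
from .evidence import EvidenceRecord
from .positional import GenomicInterval, write_bed

# ---------------------------------------------------------------------------
# Table 2 — literature evidence for genes with >= 2 independent reports.
# Cells: clinical syndrome (human), knock-out/transgenic (mouse),
# overlapping chromosome mutation (human), association studies
# (species, count), expression (rat).
# ---------------------------------------------------------------------------

_TABLE2_CELLS: dict[str, dict] = {
    "AMH": {"syndrome": True, "ko": True},
    "AMHR2": {"syndrome": True, "ko": True},
    "AR": {"syndrome": True, "ko": True, "assoc": [("human", 2)]},
    "ARID5B": {"ko": True, "expression": True},
    "BMP7": {"assoc": [("human", 1)], "expression": True},
    "EPHA4": {"ko": True, "expression": True},
    "ESR1": {"ko": True, "assoc": [("human", 2)]},
    "FGFR2": {"syndrome": True, "chrom": True, "expression": True},
    "HOXA10": {"ko": True, "assoc": [("human", 1)], "expression": True},
    "HRAS": {"syndrome": True, "chrom": True, "expression": True},
    "INSL3": {"ko": True, "assoc": [("human", 5), ("sheep", 1), ("dog", 1)]},
    "LHCGR": {"syndrome": True, "ko": True},
    "MAP2K1": {"syndrome": True, "expression": True},
    "MSX1": {"chrom": True, "expression": True},
    "NR5A1": {"ko": True, "assoc": [("human", 1)]},
    "RXFP2": {"ko": True, "assoc": [("human", 4)]},
    "SOS1": {"syndrome": True, "expression": True},
    "TNNI2": {"syndrome": True, "chrom": True},
    "TNNT3": {"syndrome": True, "chrom": True},
    "WT1": {"syndrome": True, "ko": True},
}


def table2_evidence_records() -> list[EvidenceRecord]:
    """One EvidenceRecord per independent report implied by Table 2."""
    records: list[EvidenceRecord] = []
    for gene, cells in _TABLE2_CELLS.items():
        if cells.get("syndrome"):
            records.append(
                EvidenceRecord(gene, "syndrome", "human", f"T2:{gene}:SYN:1")
            )
        if cells.get("ko"):
            records.append(
                EvidenceRecord(
                    gene, "knockout_transgenic", "mouse", f"T2:{gene}:KO:1"
                )
            )
        if cells.get("chrom"):
            records.append(
                EvidenceRecord(
                    gene, "chromosomal_aberration", "human", f"T2:{gene}:CHR:1"
                )
            )
        for species, count in cells.get("assoc", []):
            for i in range(1, count + 1):
                records.append(
                    EvidenceRecord(
                        gene, "association", species,
                        f"T2:{gene}:AS:{species}:{i}",
                    )
                )
        if cells.get("expression"):
            records.append(
                EvidenceRecord(gene, "expression", "rat", f"T2:{gene}:EXP:1")
            )
    return records


TABLE2_GENES: frozenset = frozenset(_TABLE2_CELLS)

# ---------------------------------------------------------------------------
# Table 3 — pathway analysis of the literature-collected (12 rows) and
# network-predicted (4 rows) cohorts.  (db, pathway, printed Bonferroni p,
# member genes as printed.)
# ---------------------------------------------------------------------------

_TABLE3_LITERATURE: list[tuple[str, str, str, str]] = [
    ("KEGG", "Regulation of actin cytoskeleton", "4.70E-06",
     "ACTB BRAF CDC42 CFL1 CHRM3 EZR FGD1 FGF9 FGFR1 FGFR2 HRAS ITGB1 KRAS "
     "MAP2K1 MAP2K2 MYL2 MYL9 PDGFA PFN1 PPP1CA PPP1CB PXN RAC1 RAF1 RHOA "
     "RRAS SOS1"),
    ("REACTOME", "Muscle contraction", "5.39E-06",
     "DES MYH3 MYL2 MYL3 TNNI2 TNNT2 TNNT3 TPM1 TPM3 TPM4 TTN"),
    ("KEGG", "Focal adhesion", "1.05E-05",
     "ACTB BRAF CCND1 CDC42 COL1A2 COL2A1 COL5A1 FLNA GRB2 GSK3B HRAS IGF1 "
     "ILK ITGB1 MAP2K1 MYL2 MYL9 PDGFA PPP1CA PPP1CB PXN RAC1 RAF1 RHOA "
     "SOS1 THBS4"),
    ("REACTOME", "Signaling by PDGF", "3.61E-5",
     "COL1A2 COL2A1 COL5A1 GRB2 HRAS KRAS MAP2K1 MAP2K2 PDGFA PTPN11 RAF1 "
     "SOS1 STAT3 THBS4"),
    ("REACTOME", "Signaling by insulin receptor", "7.02E-05",
     "EIF4E EIF4EBP1 GRB2 HRAS KRAS MAP2K1 MAP2K2 RAF1 RPS6 RPS6KB1 SOS1"),
    ("REACTOME", "Signaling by EGFR", "0.0022",
     "CDC42 GRB2 HRAS KRAS MAP2K1 MAP2K2 PTPN11 PXN RAF1 SOS1"),
    ("PANTHER", "RAS pathway", "0.0025",
     "BRAF CDC42 GRB2 GSK3B HRAS KRAS MAP2K1 MAP2K2 RAC1 RAF1 RHOA RRAS "
     "SOS1 STAT3"),
    ("KEGG", "Hypertrophic cardiomyopathy (HCM)", "0.0035",
     "ACTB DES IGF1 ITGB1 MYH7 MYL2 MYL3 TNNT2 TPM1 TPM3 TPM4 TTN"),
    ("BIOCARTA", "Role of MAL in Rho-mediated activation of SRF", "0.044",
     "ACTA1 CDC42 MAP2K1 MAP2K2 RAC1 RAF1 RHOA"),
    ("BIOCARTA", "IGF-1 signaling", "0.0067",
     "FOS GRB2 HRAS IGF1 MAP2K1 PTPN11 RAF1 SOS1"),
    ("PANTHER", "Integrin signaling", "0.0070",
     "BRAF CDC42 COL1A2 COL2A1 COL5A1 FLNA GRB2 HRAS ILK ITGB1 KRAS MAP2K1 "
     "MAP2K2 PXN RAC1 RAF1 RHOA RND2 RRAS SOS1"),
    ("KEGG", "Dilated cardiomyopathy", "0.0099",
     "ACTB DES IGF1 ITGB1 MYH7 MYL2 MYL3 TNNT2 TPM1 TPM3 TPM4 TTN"),
]

_TABLE3_NETWORK: list[tuple[str, str, str, str]] = [
    ("REACTOME", "Muscle contraction", "2.71E-24",
     "ACTN2 DMD MYBPC1 MYBPC2 MYBPC3 MYH8 MYL1 MYL4 NEB TCAP TMOD1 TNNC1 "
     "TNNC2 TNNI1 TNNI3 TNNT1 TPM2 VIM"),
    ("KEGG", "Hypertrophic cardiomyopathy (HCM)", "9.68E-6",
     "ACTC1 DMD MYBPC3 TGFB1 TGFB2 TGFB3 TNNC1 TNNI3 TPM2"),
    ("PANTHER", "TGF-beta signaling pathway", "1.07E-5",
     "BMP2 LEFTY1 LEFTY2 LOC100271831 MAPK1 MAPK3 MSTN NODAL TGFB1 TGFB2 "
     "TGFB3"),
    ("KEGG", "Dilated cardiomyopathy", "2.35E-5",
     "ACTC1 DMD MYBPC3 TGFB1 TGFB2 TGFB3 TNNC1 TNNI3 TPM2"),
]

# ---------------------------------------------------------------------------
# Table 4 — 12 significant pathways for the joint 222-gene cohort.
# ---------------------------------------------------------------------------

_TABLE4: list[tuple[str, str, str, str]] = [
    ("REACTOME", "Muscle contraction", "4.55E-33",
     "ACTN2 DES DMD MYBPC1 MYBPC2 MYBPC3 MYH3 MYH8 MYL1 MYL2 MYL3 MYL4 NEB "
     "TCAP TMOD1 TNNC1 TNNC2 TNNI1 TNNI2 TNNI3 TNNT1 TNNT2 TNNT3 TPM1 TPM2 "
     "TPM3 TPM4 TTN VIM"),
    ("KEGG", "Hypertrophic cardiomyopathy (HCM)", "1.21E-9",
     "ACTB ACTC1 DES DMD IGF1 ITGB1 MYBPC3 MYH7 MYL2 MYL3 TGFB1 TGFB2 TGFB3 "
     "TNNC1 TNNI3 TNNT2 TPM1 TPM2 TPM3 TPM4 TTN"),
    ("KEGG", "Dilated cardiomyopathy", "1.21E-8",
     "ACTB ACTC1 DES DMD IGF1 ITGB1 MYBPC3 MYH7 MYL2 MYL3 TGFB1 TGFB2 TGFB3 "
     "TNNC1 TNNI3 TNNT2 TPM1 TPM2 TPM3 TPM4 TTN"),
    ("KEGG", "Focal adhesion", "4.68E-7",
     "ACTB ACTN2 BRAF CAV1 CCND1 CDC42 COL1A2 COL2A1 COL5A1 FLNA GRB2 GSK3B "
     "HRAS IGF1 IGF1R ILK ITGB1 MAP2K1 MAPK1 MAPK3 MYL2 MYL9 PDGFA PPP1CA "
     "PPP1CB PRKCA PXN RAC1 RAF1 RHOA SOS1 THBS4"),
    ("REACTOME", "Signaling by insulin receptor", "3.83E-6",
     "EIF4E EIF4EBP1 GRB2 HRAS KRAS MAP2K1 MAP2K2 MAPK1 MAPK3 RAF1 RHEB "
     "RPS6 RPS6KB1 SOS1"),
    ("KEGG", "Regulation of actin cytoskeleton", "4.29E-6",
     "ACTB ACTN2 BRAF CDC42 CFL1 CHRM3 EZR FGD1 FGF3 FGF9 FGFR1 FGFR2 HRAS "
     "ITGB1 KRAS MAP2K1 MAP2K2 MAPK1 MAPK3 MYL2 MYL9 PDGFA PFN1 PPP1CA "
     "PPP1CB PXN RAC1 RAF1 RHOA RRAS SOS1"),
    ("PANTHER", "TGF-beta signaling pathway", "7.01E-6",
     "AMH AMHR2 BMP2 BMP4 BMP5 BMP7 CDC42 FOS FOXO1 FOXP3 HRAS KRAS LEFTY1 "
     "LEFTY2 MAPK1 MAPK3 MSTN NODAL RHEB RRAS TGFB1 TGFB2 TGFB3"),
    ("BIOCARTA", "Integrin signaling pathway", "1.35E-5",
     "ACTA1 ACTN2 CAV1 GRB2 HRAS ITGB1 MAP2K1 MAP2K2 MAPK1 MAPK3 PXN RAF1 "
     "RHOA SOS1"),
    ("REACTOME", "Signaling by PDGF", "7.27E-5",
     "COL2A1 COL1A2 COL5A1 GRB2 HRAS KRAS MAP2K1 MAP2K2 MAPK1 MAPK3 PDGFA "
     "PTPN11 RAF1 SOS1 STAT3 THBS4"),
    ("KEGG", "Cardiac muscle contraction", "0.0024",
     "ACTC1 MYH7 MYL2 MYL3 TNNC1 TNNI3 TNNT2 TPM1 TPM2 TPM3 TPM4"),
    ("PANTHER", "RAS pathway", "0.0030",
     "BRAF CDC42 GRB2 GSK3B HRAS KRAS MAP2K1 MAP2K2 MAPK1 MAPK3 RAC1 RAF1 "
     "RHOA RRAS SOS1 STAT3"),
    ("KEGG", "Vascular smooth muscle contraction", "0.0058",
     "ACTA2 BRAF MAP2K1 MAP2K2 MAPK1 MAPK3 MYH11 MYL9 PPP1CA PPP1CB PRKCA "
     "PRKCE RAF1 RHOA"),
]


def _to_pathways(rows: list[tuple[str, str, str, str]]) -> list[Pathway]:
    return [
        Pathway(
            id=f"{db}|{name}",
            source_db=db,
            members=frozenset(genes.split()),
            description=f"bonferroni_p={p}",
        )
        for db, name, p, genes in rows
    ]


def table3_literature_pathways() -> list[Pathway]:
    return _to_pathways(_TABLE3_LITERATURE)


def table3_network_pathways() -> list[Pathway]:
    return _to_pathways(_TABLE3_NETWORK)


def table4_pathways() -> list[Pathway]:
    return _to_pathways(_TABLE4)


def pathway_gene_lists(pathways: list[Pathway]) -> dict[str, frozenset]:
    return {p.id: p.members for p in pathways}


def printed_bonferroni(pathways: list[Pathway]) -> dict[str, float]:
    """Published Bonferroni p-values carried in the GMT description field."""
    out = {}
    for p in pathways:
        key, _, value = p.description.partition("=")
        if key == "bonferroni_p":
            out[p.id] = float(value)
    return out


# ---------------------------------------------------------------------------
# Positional candidates — representative coordinates for the printed
# aberration-overlap findings (bands only are published; these base pairs
# are synthetic stand-ins and only overlap set-identity is meaningful).
# ---------------------------------------------------------------------------

POSITIONAL_LITERATURE_GENES: tuple[str, ...] = (
    "CAPG", "MSX1", "E2F5", "PTCH1", "BICD2", "RPS6", "FGFR2", "HRAS",
    "PAX6", "WT1", "TNNI2", "TNNT3", "FLNA", "MECP2",
)
POSITIONAL_NETWORK_GENES: tuple[str, ...] = ("FHL2", "TMOD1", "MYBPC3")

_GENE_COORDS: list[tuple[str, int, int, str]] = [
    ("chr2", 85_617_000, 85_637_000, "CAPG"),
    ("chr4", 4_861_000, 4_865_000, "MSX1"),
    ("chr8", 86_110_000, 86_126_000, "E2F5"),
    ("chr9", 98_205_000, 98_280_000, "PTCH1"),
    ("chr9", 95_473_000, 95_527_000, "BICD2"),
    ("chr9", 19_376_000, 19_380_000, "RPS6"),
    ("chr10", 123_237_000, 123_357_000, "FGFR2"),
    ("chr11", 532_000, 537_000, "HRAS"),
    ("chr11", 31_806_000, 31_839_000, "PAX6"),
    ("chr11", 32_409_000, 32_457_000, "WT1"),
    ("chr11", 1_860_000, 1_864_000, "TNNI2"),
    ("chr11", 1_940_000, 1_959_000, "TNNT3"),
    ("chrX", 153_576_000, 153_603_000, "FLNA"),
    ("chrX", 153_287_000, 153_363_000, "MECP2"),
]

_NETWORK_GENE_COORDS: list[tuple[str, int, int, str]] = [
    ("chr2", 105_974_000, 106_054_000, "FHL2"),
    ("chr9", 100_090_000, 100_181_000, "TMOD1"),
    ("chr11", 47_352_000, 47_374_000, "MYBPC3"),
]

_ABERRATION_COORDS: list[tuple[str, int, int, str]] = [
    ("chr2", 85_000_000, 86_500_000, "del_2p11.2"),
    ("chr2", 105_500_000, 106_500_000, "t_2q14"),
    ("chr4", 3_000_000, 50_000_000, "dup_4p"),
    ("chr4", 46_000_000, 48_500_000, "t_4p12"),
    ("chr8", 85_500_000, 87_000_000, "inv_8q21"),
    ("chr9", 19_000_000, 20_000_000, "del_9p22"),
    ("chr9", 95_000_000, 98_500_000, "del_9q22"),
    ("chr9", 99_800_000, 100_500_000, "del_9q31"),
    ("chr10", 123_000_000, 124_000_000, "del_10q26"),
    ("chr11", 400_000, 2_100_000, "bp_11p15.5"),
    ("chr11", 31_500_000, 32_600_000, "del_11p13"),
    ("chr11", 47_000_000, 48_000_000, "del_11p11.2"),
    ("chrX", 153_000_000, 154_000_000, "del_Xq28"),
]


def _to_intervals(rows: list[tuple[str, int, int, str]]) -> list[GenomicInterval]:
    return [GenomicInterval(c, s, e, label) for c, s, e, label in rows]


def literature_gene_intervals() -> list[GenomicInterval]:
    return _to_intervals(_GENE_COORDS)


def network_gene_intervals() -> list[GenomicInterval]:
    return _to_intervals(_NETWORK_GENE_COORDS)


def aberration_intervals() -> list[GenomicInterval]:
    return _to_intervals(_ABERRATION_COORDS)


def breakpoint_11p15_interval() -> GenomicInterval:
    """The 11p15.5 breakpoint region overlapping HRAS, TNNI2 and TNNT3."""
    return next(a for a in aberration_intervals() if a.label == "bp_11p15.5")


# ---------------------------------------------------------------------------
# Cohort rosters — printed symbols padded to the stated sizes (179 / 43).
# ---------------------------------------------------------------------------

LITERATURE_COHORT_SIZE = 179
NETWORK_COHORT_SIZE = 43

# genes named in the main text beyond Tables 2-4 (association-study and
# protein-level findings)
_EXTRA_LITERATURE_GENES = frozenset({"KISS1R", "TGFBR3", "CALCB"})


def _printed_network_genes() -> set[str]:
    genes: set[str] = set()
    for p in table3_network_pathways():
        genes |= p.members
    genes |= set(POSITIONAL_NETWORK_GENES)
    return genes


def _printed_literature_genes() -> set[str]:
    genes: set[str] = set(TABLE2_GENES)
    for p in table3_literature_pathways():
        genes |= p.members
    genes |= set(POSITIONAL_LITERATURE_GENES)
    genes |= _EXTRA_LITERATURE_GENES
    # joint-analysis pathway members not attributable to the network cohort
    network = _printed_network_genes()
    for p in table4_pathways():
        genes |= p.members - network
    return genes


def network_cohort() -> list[str]:
    """The 43 network-predicted genes: printed symbols + synthetic padding."""
    printed = sorted(_printed_network_genes())
    if len(printed) > NETWORK_COHORT_SIZE:
        raise AssertionError("printed network genes exceed stated cohort size")
    padding = [
        f"SYNNET{i:02d}" for i in range(1, NETWORK_COHORT_SIZE - len(printed) + 1)
    ]
    return printed + padding


def literature_cohort() -> list[str]:
    """The 179 literature-collected genes: printed symbols + padding."""
    network = set(network_cohort())
    printed = sorted(_printed_literature_genes() - network)
    if len(printed) > LITERATURE_COHORT_SIZE:
        raise AssertionError("printed literature genes exceed stated cohort size")
    padding = [
        f"SYNLIT{i:03d}"
        for i in range(1, LITERATURE_COHORT_SIZE - len(printed) + 1)
    ]
    return printed + padding


def combined_cohort() -> set[str]:
    """Union of the literature and network cohorts (222 unique genes)."""
    return set(literature_cohort()) | set(network_cohort())


# ---------------------------------------------------------------------------
# Fixture bundle emission
# ---------------------------------------------------------------------------


def emit_paper_fixtures(out_dir) -> dict[str, Path]:
    """Write the full fixture bundle; returns {short name: path}."""
    from .evidence import write_evidence
    from .io import write_gene_list, write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _with_header(path: Path, header: str, writer) -> None:
        tmp = path.with_suffix(path.suffix + ".tmp")
        writer(tmp)
        content = tmp.read_text()
        tmp.unlink()
        path.write_text(f"# {header}\n{content}")

    p = out / "table2_evidence.tsv"
    _with_header(
        p,
        "Table 2 transcription: literature evidence, one row per "
        "independent report (approach x species x reference)",
        lambda t: write_evidence(table2_evidence_records(), t),
    )
    paths["evidence"] = p

    for key, header, pws in [
        ("table3_literature",
         "Table 3 transcription (literature-collected cohort, 12 pathways); "
         "published Bonferroni p in description", table3_literature_pathways()),
        ("table3_network",
         "Table 3 transcription (network-predicted cohort, 4 pathways); "
         "published Bonferroni p in description", table3_network_pathways()),
        ("table4_combined",
         "Table 4 transcription (joint 222-gene cohort, 12 pathways); "
         "published Bonferroni p in description", table4_pathways()),
    ]:
        p = out / f"{key}.gmt"
        _with_header(p, header, lambda t, pws=pws: write_gmt(pws, t))
        paths[key] = p

    p = out / "genes_literature.bed"
    write_bed(
        literature_gene_intervals(), p,
        header="representative coordinates (synthetic stand-ins for "
               "published cytogenetic bands): positional literature candidates",
    )
    paths["genes_literature"] = p

    p = out / "genes_network.bed"
    write_bed(
        network_gene_intervals(), p,
        header="representative coordinates (synthetic stand-ins): "
               "network-predicted positional candidates",
    )
    paths["genes_network"] = p

    p = out / "aberrations.bed"
    write_bed(
        aberration_intervals(), p,
        header="representative coordinates (synthetic stand-ins) for "
               "published chromosomal aberration / CNV regions",
    )
    paths["aberrations"] = p

    p = out / "cohort_literature_179.txt"
    write_gene_list(
        set(literature_cohort()), p,
        header="literature cohort roster: printed symbols padded with "
               "SYNLIT### synthetic placeholders to the stated size of 179",
    )
    paths["cohort_literature"] = p

    p = out / "cohort_network_43.txt"
    write_gene_list(
        set(network_cohort()), p,
        header="network-predicted roster: printed symbols padded with "
               "SYNNET## synthetic placeholders to the stated size of 43",
    )
    paths["cohort_network"] = p

    p = out / "cohort_combined_222.txt"
    write_gene_list(
        combined_cohort(), p,
        header="combined cohort (literature + network-predicted, 222 genes)",
    )
    paths["cohort_combined"] = p

    return paths
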