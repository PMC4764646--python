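"""Deterministic demonstration cohort built around the published candidates.

The bundle embeds the eight discovery-cohort observations of the reported
candidate variants (two EMR3 splice-site changes, three PTPN12 missense
observations, three LRP6 missense observations) and the single replication
variant (PTPN12 p.A105V), each with its published cDNA change, PhyloP score
and reference-panel allele counts, inside a background of noise variants
that each fail exactly one filter gate by construction. Running the full
discovery pipeline on the bundle must therefore retain exactly the eight
candidate observations, find all three genes recurrent and enriched, and
triage EMR3 at the truncating-recurrence step, PTPN12 via the driver list
and LRP6 via the mouse-screen/KEGG intersection.

Genomic positions in this bundle are synthetic placeholders: the published
table reports transcript-level changes, not genomic coordinates, and no
pipeline stage consumes absolute positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import yaml

from .io import default_gene_packs, write_cohort_manifest, write_variants_tsv
from .model import (
    CohortSpec,
    GeneListPack,
    ReferencePanelCounts,
    VariantAnnotation,
    VariantCall,
    VariantRecord,
)

#: Reference-panel cohort sizes used throughout the bundle.
PANEL_SIZES = {"inhouse": 2037, "evs": 6503, "control2": 2329, "exac": 60706}

N_DISCOVERY = 55
N_CONTROL1 = 164
N_REPLICATION = 174
N_CONTROL2 = 2329

#: (gene, sample, chrom, pos, ref, alt, transcript, cdna, prot, csq, phylop,
#:  sift, pph2, agvgd, dbsnp, {panel: allele_count})
_CANDIDATES = [
    ("EMR3", "P025", "19", 14_882_001, "G", "A", "NM_032571", "c.882+1G>A", "p.?",
     "canonical_splice", 2.427, None, None, None, None,
     {"inhouse": 0, "evs": 1, "control2": 0, "exac": 11}),
    ("EMR3", "P002", "19", 14_891_249, "A", "C", "NM_032571", "c.1249-2A>C", "p.?",
     "canonical_splice", 3.787, None, None, None, None,
     {"inhouse": 0, "evs": 0, "control2": 1, "exac": 0}),
    ("PTPN12", "P014", "7", 77_231_565, "G", "T", "NM_002835", "c.1565G>T", "p.R522M",
     "missense", 4.531, "Del.", "Prob.dam.", "C25", None,
     {"inhouse": 0, "evs": 0, "control2": 2, "exac": 0}),
    ("PTPN12", "P045", "7", 77_232_051, "C", "T", "NM_002835", "c.2051C>T", "p.S684L",
     "missense", 3.958, "Del.", "Prob.dam.", "C0", "rs201001953",
     {"inhouse": 0, "evs": 3, "control2": 3, "exac": 111}),
    ("PTPN12", "P054", "7", 77_232_051, "C", "T", "NM_002835", "c.2051C>T", "p.S684L",
     "missense", 3.958, "Del.", "Prob.dam.", "C0", "rs201001953",
     {"inhouse": 0, "evs": 3, "control2": 3, "exac": 111}),
    ("LRP6", "P002", "12", 12_300_716, "C", "A", "NM_002336", "c.716C>A", "p.W239L",
     "missense", 5.103, "Del.", "Prob.dam.", "C65", None,
     {"inhouse": 0, "evs": 0, "control2": 0, "exac": 0}),
    ("LRP6", "P001", "12", 12_302_366, "T", "C", "NM_002336", "c.2366T>C", "p.N789S",
     "missense", 6.244, "Del.", "Benign", "C55", None,
     {"inhouse": 0, "evs": 0, "control2": 0, "exac": 0}),
    ("LRP6", "P008", "12", 12_302_599, "A", "G", "NM_002336", "c.2599A>G", "p.T867A",
     "missense", 5.13, "Del.", "Benign", "C55", "rs141458215",
     {"inhouse": 0, "evs": 0, "control2": 3, "exac": 14}),
]

_REPLICATION_CANDIDATE = (
    "PTPN12", "RC204", "7", 77_230_314, "C", "T", "NM_002835", "c.314C>T", "p.A105V",
    "missense", 4.24, "Del.", "Prob.dam.", "C65", None,
    {"inhouse": 0, "evs": 0, "control2": 0, "exac": 0},
)

#: Control-2 per-gene counts of variants with a comparable predicted effect,
#: used by the replication-stage Fisher comparison (sums of the per-variant
#: control-2 allele counts above).
CONTROL2_GENE_COUNTS = {"EMR3": 1, "PTPN12": 5, "LRP6": 3}

#: Noise background: (gene, sample, chrom, pos, ref, alt, csq, phylop,
#:  failing gate). Every noise variant fails exactly the named gate.
_NOISE = [
    ("ABCA7", "P003", "19", 1_040_101, "C", "T", "missense", 4.2, "quality_depth"),
    ("ZNF99", "P011", "19", 22_941_002, "G", "A", "missense", 5.1, "quality_vr"),
    ("DNAH5", "P020", "5", 13_700_003, "T", "C", "missense", 3.9, "quality_us"),
    ("MUC4", "P031", "3", 195_500_004, "A", "G", "missense", 4.8, "quality_fraction"),
    ("PRSS1", "P007", "7", 142_457_005, "G", "A", "missense", 6.0, "frequency"),
    ("PRSS1", "P042", "7", 142_457_005, "G", "A", "missense", 6.0, "frequency"),
    ("SCN10A", "P002", "3", 38_738_006, "C", "T", "missense", 1.2, "impact_phylop"),
    ("USH2A", "P015", "1", 216_420_007, "T", "A", "synonymous", 4.4, "impact_csq"),
    ("OR2T33", "P027", "1", 248_436_008, "C", "T", "nonsense", 2.1, "lof_tolerant"),
    ("SCN10A", "P049", "3", 38_738_906, "G", "C", "missense", 0.8, "impact_phylop"),
]

_CONTROL1_NOISE = [
    ("EMR3", "C012", "19", 14_882_900, "C", "T", "missense", 1.9, "impact_phylop"),
    ("PTPN12", "C077", "7", 77_231_000, "A", "G", "synonymous", 3.4, "impact_csq"),
    ("PRSS1", "C030", "7", 142_457_005, "G", "A", "missense", 6.0, "frequency"),
    ("LRP6", "C101", "12", 12_301_000, "G", "A", "missense", 4.0, "quality_vr"),
]

_REPLICATION_NOISE = [
    ("PTPN12", "RC233", "7", 77_231_200, "T", "C", "missense", 1.5, "impact_phylop"),
    ("EMR3", "RC310", "19", 14_883_300, "G", "A", "missense", 6.1, "frequency"),
    ("LRP6", "RC355", "12", 12_301_500, "C", "G", "synonymous", 2.2, "impact_csq"),
]


@dataclass
class FixtureBundle:
    discovery_records: List[VariantRecord]
    control1_records: List[VariantRecord]
    replication_records: List[VariantRecord]
    discovery_cohort: CohortSpec
    control1_cohort: CohortSpec
    replication_cohort: CohortSpec
    packs: Dict[str, GeneListPack]
    control2_gene_counts: Dict[str, int]
    n_control2: int


def _panels(acs: Mapping[str, int]) -> Dict[str, ReferencePanelCounts]:
    return {
        panel: ReferencePanelCounts(panel, PANEL_SIZES[panel], ac)
        for panel, ac in acs.items()
    }


def _candidate_record(row) -> VariantRecord:
    (gene, sample, chrom, pos, ref, alt, transcript, cdna, prot, csq, phylop,
     sift, pph2, agvgd, dbsnp, acs) = row
    return VariantRecord(
        call=VariantCall(
            sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
            total_reads=80, variant_reads=41, unique_starts=14,
        ),
        annotation=VariantAnnotation(
            gene_symbol=gene, transcript=transcript, cdna_change=cdna,
            protein_change=prot, consequence=csq, phylop=phylop,
            sift_label=sift, polyphen_label=pph2, agvgd_class=agvgd,
            dbsnp_id=dbsnp,
        ),
        panels=_panels(acs),
    )


def _noise_record(row) -> VariantRecord:
    gene, sample, chrom, pos, ref, alt, csq, phylop, failing = row
    dp, vr, us = 60, 30, 12
    acs = {"inhouse": 0, "evs": 0}
    if failing == "quality_depth":
        dp, vr, us = 8, 8, 12
    elif failing == "quality_vr":
        dp, vr, us = 60, 3, 12
    elif failing == "quality_us":
        dp, vr, us = 60, 30, 2
    elif failing == "quality_fraction":
        dp, vr, us = 100, 20, 12
    elif failing == "frequency":
        acs = {"inhouse": 0, "evs": 40}  # EVS MAF 40/13006 > 0.001
    # impact_phylop / impact_csq / lof_tolerant fail downstream gates as-is
    return VariantRecord(
        call=VariantCall(
            sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
            total_reads=dp, variant_reads=vr, unique_starts=us,
        ),
        annotation=VariantAnnotation(
            gene_symbol=gene, transcript="", cdna_change="", protein_change="",
            consequence=csq, phylop=phylop,
        ),
        panels=_panels(acs),
    )


def make_paper_fixture(
    packs: Optional[Dict[str, GeneListPack]] = None,
) -> FixtureBundle:
    """Build the deterministic demonstration bundle in memory.

    Two invocations return equal content; writing the bundle twice yields
    byte-identical files.
    """
    if packs is None:
        packs = default_gene_packs()
    discovery = [_candidate_record(r) for r in _CANDIDATES]
    discovery += [_noise_record(r) for r in _NOISE]
    control1 = [_noise_record(r) for r in _CONTROL1_NOISE]
    replication = [_candidate_record(_REPLICATION_CANDIDATE)]
    replication += [_noise_record(r) for r in _REPLICATION_NOISE]

    discovery_cohort = CohortSpec(
        "discovery", "discovery",
        {f"P{i + 1:03d}": f"FAM{i + 1:03d}" for i in range(N_DISCOVERY)},
    )
    control1_cohort = CohortSpec(
        "control1", "control",
        {f"C{i + 1:03d}": f"CF{i + 1:03d}" for i in range(N_CONTROL1)},
    )
    replication_cohort = CohortSpec(
        "replication", "replication",
        {f"RC{i + 201}": f"RF{i + 201}" for i in range(N_REPLICATION)},
    )
    return FixtureBundle(
        discovery_records=discovery,
        control1_records=control1,
        replication_records=replication,
        discovery_cohort=discovery_cohort,
        control1_cohort=control1_cohort,
        replication_cohort=replication_cohort,
        packs=packs,
        control2_gene_counts=dict(CONTROL2_GENE_COUNTS),
        n_control2=N_CONTROL2,
    )


def write_fixture(outdir) -> Dict[str, Path]:
    """Write the bundle as TSV tables, manifests and pack files."""
    bundle = make_paper_fixture()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "discovery": outdir / "discovery_variants.tsv",
        "control1": outdir / "control1_variants.tsv",
        "replication": outdir / "replication_variants.tsv",
        "manifest": outdir / "cohorts.tsv",
        "packs": outdir / "packs",
    }
    write_variants_tsv(bundle.discovery_records, paths["discovery"])
    write_variants_tsv(bundle.control1_records, paths["control1"])
    write_variants_tsv(bundle.replication_records, paths["replication"])
    write_cohort_manifest(
        [bundle.discovery_cohort, bundle.control1_cohort, bundle.replication_cohort],
        paths["manifest"],
    )
    packs_dir = paths["packs"]
    packs_dir.mkdir(exist_ok=True)
    manifest_lines = ["list_id\tfilename"]
    for list_id, pack in sorted(bundle.packs.items()):
        filename = f"{list_id}.txt"
        (packs_dir / filename).write_text(
            "\n".join(sorted(pack.symbols)) + "\n", encoding="utf-8"
        )
        manifest_lines.append(f"{list_id}\t{filename}")
    (packs_dir / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")

    config = {
        "case_variants": str(paths["discovery"]),
        "control_variants": str(paths["control1"]),
        "replication_variants": str(paths["replication"]),
        "manifest": str(paths["manifest"]),
        "packs_dir": str(packs_dir),
        "out_dir": str(outdir / "report"),
        "control2_gene_counts": dict(bundle.control2_gene_counts),
        "n_control2": bundle.n_control2,
    }
    paths["config"] = outdir / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=True))
    return paths
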