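"""Readers and writers for the formats every pipeline stage touches.

Two input dialects carry annotated per-sample variant observations:

* ``tsv`` — a flat table with one row per sample-variant observation.
  Header: ``sample_id chrom pos ref alt total_reads variant_reads
  unique_starts gene transcript cdna prot csq phylop sift pph2 agvgd
  dbsnp`` followed by ``ac_<panel>``/``n_<panel>`` column pairs, one pair
  per reference panel. Empty string means *absent*, never zero.
* ``vcf`` — VCF 4.x with per-sample FORMAT fields ``DP`` (total reads),
  ``VR`` (variant reads), ``US`` (unique starts) and INFO keys ``GENE``,
  ``TRANSCRIPT``, ``CDNA``, ``PROT``, ``CSQ``, ``PHYLOP``, ``SIFT``,
  ``PPH2``, ``AGVGD``, ``DBSNP`` plus ``AC_<panel>``/``N_<panel>`` pairs.
  A sample contributes one observation per site where its ``VR`` value is
  present and positive.

Gene lists are plain text, one symbol per line, ``#`` comments allowed.
Cohort manifests are TSV with columns ``sample_id cohort_id role family_id``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set

import pandas as pd

from .model import (
    CONSEQUENCES,
    CohortSpec,
    DataModelError,
    GENE_LIST_IDS,
    GeneListPack,
    ReferencePanelCounts,
    VariantAnnotation,
    VariantCall,
    VariantRecord,
)

TSV_FIXED_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "total_reads", "variant_reads", "unique_starts",
    "gene", "transcript", "cdna", "prot", "csq",
    "phylop", "sift", "pph2", "agvgd", "dbsnp",
]


class FormatError(ValueError):
    """Raised for malformed input files; names the offending line."""


def compute_maf(allele_count: int, n_individuals: int) -> float:
    """Minor allele frequency: allele count over chromosome count 2N.

    Returned to 7 significant digits, matching the rendering convention of
    published frequency tables.

    >>> compute_maf(1, 55)
    0.009090909
    >>> compute_maf(111, 60706)
    0.0009142424
    """
    if n_individuals <= 0:
        raise DataModelError("n_individuals must be > 0")
    if not 0 <= allele_count <= 2 * n_individuals:
        raise DataModelError(
            f"allele_count {allele_count} outside [0, {2 * n_individuals}]"
        )
    maf = allele_count / (2 * n_individuals)
    return float(f"{maf:.7g}")


# ---------------------------------------------------------------------------
# gene lists and packs


def read_gene_list(path) -> Set[str]:
    """Read a plain-text gene list: one symbol per line, '#' comments.

    Symbols are upper-cased and de-duplicated. An empty result is an error:
    an empty evidence list would silently disable a triage step.
    """
    path = Path(path)
    symbols: Set[str] = set()
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            symbols.add(line.upper())
    if not symbols:
        raise FormatError(f"gene list {path} contains no symbols")
    return symbols


def read_gene_packs(directory) -> Dict[str, GeneListPack]:
    """Load evidence gene-list packs from a directory with a manifest.

    ``manifest.tsv`` has columns ``list_id`` and ``filename``; each named
    file is read with :func:`read_gene_list`.
    """
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if not manifest.exists():
        raise FormatError(f"pack manifest not found: {manifest}")
    packs: Dict[str, GeneListPack] = {}
    for lineno, raw in enumerate(manifest.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.startswith("list_id"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{manifest} line {lineno}: expected 2 columns")
        list_id, filename = parts[0].strip(), parts[1].strip()
        if list_id not in GENE_LIST_IDS:
            raise FormatError(
                f"{manifest} line {lineno}: unknown list_id {list_id!r}; "
                f"accepted: {', '.join(GENE_LIST_IDS)}"
            )
        packs[list_id] = GeneListPack(list_id, frozenset(read_gene_list(directory / filename)))
    return packs


def default_gene_packs() -> Dict[str, GeneListPack]:
    """Evidence packs shipped with the package (editable plain-text files)."""
    from importlib.resources import files

    return read_gene_packs(files("crcburden") / "packs")


# ---------------------------------------------------------------------------
# cohort manifests


def read_cohort_manifest(path) -> Dict[str, CohortSpec]:
    """Read a cohort manifest TSV into ``{cohort_id: CohortSpec}``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cohort_id", "role", "family_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    cohorts: Dict[str, CohortSpec] = {}
    for cohort_id, sub in df.groupby("cohort_id", sort=True):
        roles = set(sub["role"])
        if len(roles) != 1:
            raise FormatError(f"{path}: cohort {cohort_id} has mixed roles {sorted(roles)}")
        if sub["sample_id"].duplicated().any():
            dup = sub.loc[sub["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"{path}: duplicate sample_id {dup!r} in cohort {cohort_id}")
        families = dict(zip(sub["sample_id"], sub["family_id"]))
        cohorts[str(cohort_id)] = CohortSpec(str(cohort_id), roles.pop(), families)
    return cohorts


def write_cohort_manifest(cohorts: Iterable[CohortSpec], path) -> None:
    rows = []
    for cohort in cohorts:
        for sample_id, family_id in cohort.families.items():
            rows.append((sample_id, cohort.cohort_id, cohort.role, family_id))
    pd.DataFrame(rows, columns=["sample_id", "cohort_id", "role", "family_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# variant tables


def _parse_optional_float(text: str) -> Optional[float]:
    return None if text == "" else float(text)


def _parse_optional_int(text: str) -> Optional[int]:
    return None if text == "" else int(text)


def _parse_optional_str(text: str) -> Optional[str]:
    return None if text == "" else text


def read_annotated_variants(path, dialect: str = "tsv") -> List[VariantRecord]:
    """Read annotated per-sample variant observations.

    Parameters
    ----------
    path : path-like
        Input file in one of the two supported dialects.
    dialect : {"tsv", "vcf"}

    Returns
    -------
    list of VariantRecord, one per sample-variant observation, with 1-based
    coordinates preserved and absent optional fields represented as ``None``.
    """
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'vcf'")


def _read_tsv(path) -> List[VariantRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    panel_ids = []
    for col in df.columns:
        if col.startswith("ac_"):
            panel = col[3:]
            if f"n_{panel}" not in df.columns:
                raise FormatError(f"{path}: column ac_{panel} has no matching n_{panel}")
            panel_ids.append(panel)

    records: List[VariantRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        lineno = idx + 2  # header is line 1
        row = dict(zip(df.columns, row))
        try:
            if row["csq"] not in CONSEQUENCES:
                raise DataModelError(
                    f"unknown consequence {row['csq']!r}; accepted terms: "
                    + ", ".join(sorted(CONSEQUENCES))
                )
            call = VariantCall(
                sample_id=row["sample_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                total_reads=int(row["total_reads"]),
                variant_reads=int(row["variant_reads"]),
                unique_starts=_parse_optional_int(row["unique_starts"]),
            )
            annotation = VariantAnnotation(
                gene_symbol=row["gene"],
                transcript=row["transcript"],
                cdna_change=row["cdna"],
                protein_change=row["prot"],
                consequence=row["csq"],
                phylop=_parse_optional_float(row["phylop"]),
                sift_label=_parse_optional_str(row["sift"]),
                polyphen_label=_parse_optional_str(row["pph2"]),
                agvgd_class=_parse_optional_str(row["agvgd"]),
                dbsnp_id=_parse_optional_str(row["dbsnp"]),
            )
            panels = {}
            for panel in panel_ids:
                ac, n = row[f"ac_{panel}"], row[f"n_{panel}"]
                if ac == "" and n == "":
                    continue
                if ac == "" or n == "":
                    raise DataModelError(f"panel {panel}: ac/n pair incomplete")
                panels[panel] = ReferencePanelCounts(panel, int(n), int(ac))
        except (DataModelError, ValueError) as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from exc
        records.append(VariantRecord(call, annotation, panels))
    return records


def write_variants_tsv(records: Iterable[VariantRecord], path) -> None:
    """Write records in the TSV dialect; inverse of the ``tsv`` reader."""
    records = list(records)
    panel_ids = sorted({p for r in records for p in r.panels})
    columns = TSV_FIXED_COLUMNS + [c for p in panel_ids for c in (f"ac_{p}", f"n_{p}")]

    def blank_if_none(value):
        return "" if value is None else value

    rows = []
    for r in records:
        row = {
            "sample_id": r.call.sample_id,
            "chrom": r.call.chrom,
            "pos": r.call.pos,
            "ref": r.call.ref,
            "alt": r.call.alt,
            "total_reads": r.call.total_reads,
            "variant_reads": r.call.variant_reads,
            "unique_starts": blank_if_none(r.call.unique_starts),
            "gene": r.annotation.gene_symbol,
            "transcript": r.annotation.transcript,
            "cdna": r.annotation.cdna_change,
            "prot": r.annotation.protein_change,
            "csq": r.annotation.consequence,
            "phylop": blank_if_none(r.annotation.phylop),
            "sift": blank_if_none(r.annotation.sift_label),
            "pph2": blank_if_none(r.annotation.polyphen_label),
            "agvgd": blank_if_none(r.annotation.agvgd_class),
            "dbsnp": blank_if_none(r.annotation.dbsnp_id),
        }
        for p in panel_ids:
            counts = r.panels.get(p)
            row[f"ac_{p}"] = "" if counts is None else counts.allele_count
            row[f"n_{p}"] = "" if counts is None else counts.n_individuals
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def _read_vcf(path) -> List[VariantRecord]:
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    records: List[VariantRecord] = []
    for variant in vcf:
        info = dict(variant.INFO)
        csq = info.get("CSQ")
        if csq is None:
            raise FormatError(f"{path} {variant.CHROM}:{variant.POS}: missing INFO CSQ")
        if csq not in CONSEQUENCES:
            raise FormatError(
                f"{path} {variant.CHROM}:{variant.POS}: unknown consequence "
                f"{csq!r}; accepted terms: " + ", ".join(sorted(CONSEQUENCES))
            )
        panels = {}
        for key, value in info.items():
            if key.startswith("AC_"):
                panel = key[3:]
                n = info.get(f"N_{panel}")
                if n is None:
                    raise FormatError(
                        f"{path} {variant.CHROM}:{variant.POS}: AC_{panel} has no N_{panel}"
                    )
                panels[panel.lower()] = ReferencePanelCounts(
                    panel.lower(), int(n), int(value)
                )
        phylop = info.get("PHYLOP")
        annotation = VariantAnnotation(
            gene_symbol=str(info.get("GENE", "")),
            transcript=str(info.get("TRANSCRIPT", "")),
            cdna_change=str(info.get("CDNA", "")),
            protein_change=str(info.get("PROT", "")),
            consequence=csq,
            phylop=None if phylop is None else float(phylop),
            sift_label=info.get("SIFT"),
            polyphen_label=info.get("PPH2"),
            agvgd_class=info.get("AGVGD"),
            dbsnp_id=None if variant.ID in (None, ".") else variant.ID,
        )
        dp = variant.format("DP")
        vr = variant.format("VR")
        us = variant.format("US")
        if dp is None or vr is None:
            raise FormatError(
                f"{path} {variant.CHROM}:{variant.POS}: FORMAT DP/VR required"
            )
        for i, sample in enumerate(samples):
            vr_i = int(vr[i][0])
            if vr_i <= 0:  # missing (negative sentinel) or non-carrier
                continue
            us_i = None
            if us is not None:
                raw = int(us[i][0])
                us_i = raw if raw >= 0 else None
            try:
                call = VariantCall(
                    sample_id=sample,
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=variant.ALT[0],
                    total_reads=int(dp[i][0]),
                    variant_reads=vr_i,
                    unique_starts=us_i,
                )
            except DataModelError as exc:
                raise FormatError(
                    f"{path} {variant.CHROM}:{variant.POS} sample {sample}: {exc}"
                ) from exc
            records.append(VariantRecord(call, annotation, panels))
    return records
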