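"""End-to-end orchestration: discovery screen and replication comparison.

``run_discovery`` executes filter -> biallelic detection -> recurrence ->
burden screen -> known-gene annotation -> triage -> report, logging the
record count entering and leaving every stage (the funnel). The control
cohort is filtered under the same configuration; the burden stage refuses
to compare cohorts whose filter fingerprints differ.

``run_replication`` applies the replication selection rule to targeted
resequencing calls of the candidate genes and compares per-gene carrier
counts against a high-coverage control panel with Fisher's exact test,
Benjamini-Hochberg corrected over the candidate genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import yaml

from .burden import (
    BurdenScreenResult,
    FisherResult,
    benjamini_hochberg,
    burden_screen,
    fisher_exact_carriers,
)
from .filtering import FilterConfig, FilterResult, filter_cohort
from .io import (
    read_annotated_variants,
    read_cohort_manifest,
    read_gene_packs,
    default_gene_packs,
)
from .model import CohortSpec, FilteredVariant, GeneListPack
from .triage import (
    KnownGeneHit,
    TriageResult,
    annotate_known_genes,
    select_replication_variants,
    triage_candidates,
    write_candidate_report,
)
from .zygosity import RecurrenceRecord, find_biallelic_candidates, find_recurrent_genes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and settings for an end-to-end run (YAML-serialisable)."""

    case_variants: str = ""
    control_variants: str = ""
    replication_variants: str = ""
    manifest: str = ""
    packs_dir: str = ""
    out_dir: str = "results"
    dialect: str = "tsv"
    filter: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.05
    burden_unit: str = "variants"
    m_policy: str = "recurrent_genes"  # or an explicit integer
    replication_quality_gate: bool = False
    control2_gene_counts: Dict[str, int] = field(default_factory=dict)
    n_control2: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        filt = raw.pop("filter", {})
        config = cls(**raw)
        if filt:
            config.filter = FilterConfig(**filt)
        return config

    def load_packs(self) -> Dict[str, GeneListPack]:
        if self.packs_dir:
            return read_gene_packs(self.packs_dir)
        return default_gene_packs()


@dataclass
class DiscoveryResult:
    filter_result: FilterResult
    control_filter_result: FilterResult
    biallelic: Dict[str, Dict[str, str]]  # sample -> {gene: mechanism}
    recurrence: List[RecurrenceRecord]
    burden: BurdenScreenResult
    known_hits: List[KnownGeneHit]
    triage: List[TriageResult]
    report_paths: Optional[Dict[str, Path]] = None

    @property
    def candidate_genes(self) -> List[str]:
        return [t.gene_symbol for t in self.triage if t.retained_at_step != "none"]


def run_discovery_from_records(
    case_records,
    control_records,
    case_cohort: CohortSpec,
    control_cohort: CohortSpec,
    packs: Mapping[str, GeneListPack],
    filter_config: Optional[FilterConfig] = None,
    alpha: float = 0.05,
    burden_unit: str = "variants",
    m: Optional[int] = None,
    out_dir=None,
) -> DiscoveryResult:
    """Discovery pipeline over in-memory records (the library entry point)."""
    if filter_config is None:
        filter_config = FilterConfig()
    lof = packs.get("lof_tolerant")

    case_filtered = filter_cohort(
        case_records, filter_config, lof_tolerant=lof,
        sample_ids=case_cohort.sample_ids,
    )
    logger.info("case filter funnel: %s", case_filtered.funnel)
    control_filtered = filter_cohort(control_records, filter_config, lof_tolerant=lof)
    logger.info("control filter funnel: %s", control_filtered.funnel)

    biallelic: Dict[str, Dict[str, str]] = {}
    by_sample: Dict[str, List[FilteredVariant]] = {}
    for fv in case_filtered.retained:
        by_sample.setdefault(fv.sample_id, []).append(fv)
    for sample, fvs in sorted(by_sample.items()):
        genes = find_biallelic_candidates(fvs)
        if genes:
            biallelic[sample] = genes
    logger.info("biallelic candidates in %d samples", len(biallelic))

    recurrence = find_recurrent_genes(case_filtered.retained, case_cohort)
    logger.info("recurrently affected genes: %d", len(recurrence))

    burden = burden_screen(
        recurrence,
        n_case=case_cohort.n_individuals,
        control_variants=control_filtered.retained,
        n_control=control_cohort.n_individuals,
        alpha=alpha,
        m=m,
        unit=burden_unit,
        case_fingerprint=case_filtered.config_fingerprint,
        control_fingerprint=control_filtered.config_fingerprint,
    )
    logger.info(
        "burden screen: %d retained, %d removed",
        len(burden.retained_genes), len(burden.removed_genes),
    )

    known_hits = annotate_known_genes(case_filtered.retained, packs)
    survivors = [r for r in recurrence if r.gene_symbol in set(burden.retained_genes)]
    triage = triage_candidates(survivors, packs)
    logger.info(
        "triage: %s",
        {t.gene_symbol: t.retained_at_step for t in triage},
    )

    result = DiscoveryResult(
        filter_result=case_filtered,
        control_filter_result=control_filtered,
        biallelic=biallelic,
        recurrence=recurrence,
        burden=burden,
        known_hits=known_hits,
        triage=triage,
    )
    if out_dir is not None:
        result.report_paths = write_candidate_report(
            out_dir,
            filter_summary=case_filtered.summary,
            funnel=case_filtered.funnel,
            biallelic=biallelic,
            recurrence=recurrence,
            burden=burden,
            known_hits=known_hits,
            triage=triage,
        )
    return result


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """Discovery pipeline from files named in a :class:`PipelineConfig`."""
    cohorts = read_cohort_manifest(config.manifest)
    case_cohort = _cohort_with_role(cohorts, "discovery")
    control_cohort = _cohort_with_role(cohorts, "control")
    case_records = read_annotated_variants(config.case_variants, config.dialect)
    control_records = read_annotated_variants(config.control_variants, config.dialect)
    m = None if config.m_policy == "recurrent_genes" else int(config.m_policy)
    return run_discovery_from_records(
        case_records, control_records, case_cohort, control_cohort,
        packs=config.load_packs(),
        filter_config=config.filter,
        alpha=config.alpha,
        burden_unit=config.burden_unit,
        m=m,
        out_dir=config.out_dir,
    )


@dataclass
class ReplicationResult:
    selected: List[FilteredVariant]
    fisher: List[FisherResult]
    adjusted_p: Dict[str, float]
    significant: Dict[str, bool]
    skipped: bool = False


def run_replication_from_records(
    replication_records,
    candidate_genes: Sequence[str],
    replication_cohort: CohortSpec,
    control2_gene_counts: Mapping[str, int],
    n_control2: int,
    filter_config: Optional[FilterConfig] = None,
    apply_quality: bool = False,
    alpha: float = 0.05,
) -> ReplicationResult:
    """Replication stage: selection rule, then per-gene Fisher vs control-2.

    Carrier counts in the replication cohort are compared with counts of
    comparably damaging variants in the control panel; BH correction runs
    over the candidate genes (m = number of candidates).
    """
    candidate_genes = [g.upper() for g in candidate_genes]
    records = [r for r in replication_records if r.gene in candidate_genes]
    if filter_config is None:
        filter_config = FilterConfig(frequency_panels=("evs",))
    selected = select_replication_variants(
        records, filter_config, apply_quality=apply_quality
    )
    for fv in selected:
        replication_cohort.family_of(fv.sample_id)  # unknown sample -> error
    if not selected:
        logger.info("no qualifying replication variants; Fisher stage skipped")
        return ReplicationResult(
            selected=[], fisher=[], adjusted_p={}, significant={}, skipped=True
        )

    carriers: Dict[str, set] = {g: set() for g in candidate_genes}
    for fv in selected:
        carriers[fv.gene].add(fv.sample_id)
    fisher = [
        fisher_exact_carriers(
            len(carriers[gene]),
            replication_cohort.n_individuals,
            int(control2_gene_counts.get(gene, 0)),
            n_control2,
            gene_symbol=gene,
        )
        for gene in candidate_genes
    ]
    bh = benjamini_hochberg(
        [f.p_value for f in fisher], alpha=alpha, m=len(candidate_genes)
    )
    return ReplicationResult(
        selected=selected,
        fisher=fisher,
        adjusted_p={g: item.adjusted_p for g, item in zip(candidate_genes, bh)},
        significant={g: item.significant for g, item in zip(candidate_genes, bh)},
    )


def run_replication(
    config: PipelineConfig, candidate_genes: Sequence[str]
) -> ReplicationResult:
    cohorts = read_cohort_manifest(config.manifest)
    replication_cohort = _cohort_with_role(cohorts, "replication")
    records = read_annotated_variants(config.replication_variants, config.dialect)
    filt = FilterConfig(
        min_total_reads=config.filter.min_total_reads,
        min_variant_reads=config.filter.min_variant_reads,
        min_unique_starts=config.filter.min_unique_starts,
        min_variant_fraction=config.filter.min_variant_fraction,
        max_panel_maf=config.filter.max_panel_maf,
        phylop_min=config.filter.phylop_min,
        frequency_panels=("evs",),
    )
    return run_replication_from_records(
        records,
        candidate_genes,
        replication_cohort,
        control2_gene_counts=config.control2_gene_counts,
        n_control2=config.n_control2,
        filter_config=filt,
        apply_quality=config.replication_quality_gate,
        alpha=config.alpha,
    )


def _cohort_with_role(cohorts: Mapping[str, CohortSpec], role: str) -> CohortSpec:
    matching = [c for c in cohorts.values() if c.role == role]
    if len(matching) != 1:
        raise ValueError(
            f"manifest must define exactly one {role} cohort, found {len(matching)}"
        )
    return matching[0]
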