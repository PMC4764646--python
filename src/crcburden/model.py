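"""Shared data model for cohort rare-variant analysis.

A *record* in this package is one sequenced allele observation in one
sample (``VariantCall``), plus the gene/consequence/conservation metadata
attached to it (``VariantAnnotation``) and the allele counts observed in
one or more population reference panels (``ReferencePanelCounts``).
Coordinates are 1-based throughout (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

#: Controlled consequence vocabulary. ``canonical_splice`` means a change at
#: the +/-1 or +/-2 intronic positions of an exon boundary; the annotation
#: source encodes this upstream.
CONSEQUENCES = frozenset(
    {"nonsense", "frameshift", "canonical_splice", "missense", "synonymous", "other"}
)

#: Consequences treated as protein truncating.
TRUNCATING_CONSEQUENCES = frozenset({"nonsense", "frameshift", "canonical_splice"})

#: Insertions/deletions never carry a unique-starts count (substitutions only).
INDEL_CONSEQUENCES = frozenset({"frameshift"})

#: Recognised gene-list identifiers for evidence packs.
GENE_LIST_IDS = (
    "crc_predisposition",
    "cancer_syndrome",
    "lof_tolerant",
    "crc_driver",
    "mouse_transposon",
    "kegg_cancer_pathways",
    "gwas",
)

COHORT_ROLES = frozenset({"discovery", "replication", "control"})


class DataModelError(ValueError):
    """Raised when a record violates a data-model invariant."""


@dataclass(frozen=True)
class VariantCall:
    """One allele observation in one sample with its read-level evidence.

    Parameters
    ----------
    sample_id : str
        Sample carrying the allele.
    chrom, pos, ref, alt
        1-based genomic coordinate and alleles.
    total_reads : int
        Read depth at the site.
    variant_reads : int
        Reads supporting the alternate allele.
    unique_starts : int, optional
        Distinct read start positions supporting the variant; available
        for substitutions only and absent (``None``) for indels.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    total_reads: int
    variant_reads: int
    unique_starts: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataModelError(f"pos must be >= 1, got {self.pos}")
        if self.total_reads < 0 or self.variant_reads < 0:
            raise DataModelError("read counts must be non-negative")
        if self.variant_reads > self.total_reads:
            raise DataModelError(
                f"variant_reads ({self.variant_reads}) exceeds total_reads "
                f"({self.total_reads}) for {self.sample_id} {self.chrom}:{self.pos}"
            )
        if self.unique_starts is not None and self.unique_starts < 0:
            raise DataModelError("unique_starts must be non-negative when present")

    @property
    def variant_read_fraction(self) -> float:
        """Fraction of reads supporting the alternate allele, in [0, 1]."""
        if self.total_reads == 0:
            return 0.0
        return self.variant_reads / self.total_reads

    @property
    def variant_key(self) -> tuple:
        """Identity of the variant itself (sample-independent)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantAnnotation:
    """Gene/transcript/consequence/conservation metadata for one variant.

    ``phylop`` is the vertebrate conservation score consumed as input; it is
    expected for missense records and ignored for truncating consequences.
    The in-silico predictor labels (SIFT, PolyPhen-2, Align-GVGD) are carried
    through for reporting but are never used as filters.
    """

    gene_symbol: str
    transcript: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    consequence: str = "other"
    phylop: Optional[float] = None
    sift_label: Optional[str] = None
    polyphen_label: Optional[str] = None
    agvgd_class: Optional[str] = None
    dbsnp_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise DataModelError(
                f"unknown consequence {self.consequence!r}; accepted terms: "
                + ", ".join(sorted(CONSEQUENCES))
            )
        object.__setattr__(self, "gene_symbol", self.gene_symbol.upper())


@dataclass(frozen=True)
class ReferencePanelCounts:
    """Allele count and cohort size for one population reference panel."""

    panel_id: str
    n_individuals: int
    allele_count: int

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise DataModelError(f"panel {self.panel_id}: n_individuals must be > 0")
        if not 0 <= self.allele_count <= 2 * self.n_individuals:
            raise DataModelError(
                f"panel {self.panel_id}: allele_count {self.allele_count} outside "
                f"[0, {2 * self.n_individuals}]"
            )

    @property
    def maf(self) -> float:
        from .io import compute_maf  # local import to avoid a cycle

        return compute_maf(self.allele_count, self.n_individuals)


@dataclass(frozen=True)
class VariantRecord:
    """One sample-variant observation: call + annotation + panel counts."""

    call: VariantCall
    annotation: VariantAnnotation
    panels: Mapping[str, ReferencePanelCounts] = field(default_factory=dict)

    @property
    def gene(self) -> str:
        return self.annotation.gene_symbol

    @property
    def sample_id(self) -> str:
        return self.call.sample_id

    @property
    def variant_key(self) -> tuple:
        return self.call.variant_key

    def with_sample(self, sample_id: str) -> "VariantRecord":
        return VariantRecord(
            call=replace(self.call, sample_id=sample_id),
            annotation=self.annotation,
            panels=self.panels,
        )


@dataclass(frozen=True)
class FilteredVariant:
    """A record that survived the filter cascade, with its impact class."""

    record: VariantRecord
    impact_class: str  # "truncating" | "conserved_missense"

    @property
    def gene(self) -> str:
        return self.record.gene

    @property
    def sample_id(self) -> str:
        return self.record.sample_id

    @property
    def variant_key(self) -> tuple:
        return self.record.variant_key


@dataclass(frozen=True)
class CohortSpec:
    """A named cohort with its role and sample-to-family assignment."""

    cohort_id: str
    role: str
    families: Mapping[str, str]  # sample_id -> family_id

    def __post_init__(self) -> None:
        if self.role not in COHORT_ROLES:
            raise DataModelError(
                f"cohort {self.cohort_id}: unknown role {self.role!r}; "
                f"accepted: {sorted(COHORT_ROLES)}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.families)

    @property
    def sample_ids(self) -> list:
        return list(self.families)

    def family_of(self, sample_id: str) -> str:
        try:
            return self.families[sample_id]
        except KeyError:
            raise DataModelError(
                f"sample {sample_id!r} missing from cohort manifest "
                f"{self.cohort_id!r}"
            ) from None


@dataclass(frozen=True)
class GeneListPack:
    """A named evidence gene list (case-normalised, non-empty)."""

    list_id: str
    symbols: frozenset

    def __post_init__(self) -> None:
        if not self.symbols:
            raise DataModelError(f"gene list {self.list_id!r} is empty")
        object.__setattr__(
            self, "symbols", frozenset(s.upper() for s in self.symbols)
        )

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols
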