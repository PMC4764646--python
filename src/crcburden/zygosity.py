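"""Biallelic-gene detection and cross-sample recurrence.

Zygosity is called from the variant-read fraction alone (no genotype
likelihoods): an autosomal call with >= 95% variant reads is treated as
homozygous, everything else as heterozygous. Compound heterozygotes are
*putative* — read-backed phasing is unavailable, so two distinct
heterozygous variants in one gene in one individual are reported as a
candidate recessive hit pending orthogonal confirmation.

A gene is *recurrent* when qualifying variants occur in at least two
carriers from distinct families; an identical variant shared by two
unrelated carriers counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .model import CohortSpec, FilteredVariant, VariantCall

HOMOZYGOUS_FRACTION = 0.95

MECHANISM_HOM = "homozygous"
MECHANISM_COMPOUND_HET = "putative_compound_het"

_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def is_autosome(chrom: str) -> bool:
    """True for chromosomes 1-22, with or without a ``chr`` prefix."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name in _AUTOSOMES


@dataclass(frozen=True)
class ZygosityCall:
    state: str  # "het" | "hom"
    basis: float  # variant_read_fraction the call rests on


@dataclass(frozen=True)
class RecurrenceRecord:
    """One recurrently affected gene and the evidence behind it."""

    gene_symbol: str
    carrier_sample_ids: Tuple[str, ...]
    carrier_family_ids: Tuple[str, ...]
    variants: Tuple[FilteredVariant, ...]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_carriers(self) -> int:
        return len(set(self.carrier_sample_ids))

    @property
    def n_unrelated_carriers(self) -> int:
        return len(set(self.carrier_family_ids))


def call_zygosity(call: VariantCall, chrom_is_autosome: bool) -> ZygosityCall:
    """Classify a call as homozygous or heterozygous from read support.

    Homozygosity requires an autosome and a variant-read fraction of at
    least 95% (inclusive); sex-chromosome calls are always reported het
    since hemizygosity cannot be distinguished without sex information.
    """
    fraction = call.variant_read_fraction
    if chrom_is_autosome and fraction >= HOMOZYGOUS_FRACTION:
        return ZygosityCall("hom", fraction)
    return ZygosityCall("het", fraction)


def find_biallelic_candidates(
    sample_records: Sequence[FilteredVariant],
) -> Dict[str, str]:
    """Genes plausibly hit on both alleles in one sample.

    A gene qualifies through a homozygous variant, or through two or more
    *distinct* heterozygous variants (same chrom/pos/ref/alt counted once).
    Input records must all belong to one sample and have already passed the
    filter cascade.

    Returns ``{gene_symbol: mechanism}`` with mechanism ``homozygous`` or
    ``putative_compound_het`` (homozygous takes precedence).
    """
    samples = {fv.sample_id for fv in sample_records}
    if len(samples) > 1:
        raise ValueError(f"records span multiple samples: {sorted(samples)}")
    hom_genes = set()
    het_variants: Dict[str, set] = defaultdict(set)
    for fv in sample_records:
        zyg = call_zygosity(fv.record.call, is_autosome(fv.record.call.chrom))
        if zyg.state == "hom":
            hom_genes.add(fv.gene)
        else:
            het_variants[fv.gene].add(fv.variant_key)
    result: Dict[str, str] = {}
    for gene in hom_genes:
        result[gene] = MECHANISM_HOM
    for gene, keys in het_variants.items():
        if gene not in result and len(keys) >= 2:
            result[gene] = MECHANISM_COMPOUND_HET
    return result


def find_recurrent_genes(
    records: Iterable[FilteredVariant],
    manifest: CohortSpec,
    require_unrelated_carriers: bool = True,
) -> List[RecurrenceRecord]:
    """Genes with qualifying variants in at least two distinct families.

    Carriers are de-duplicated per gene per sample; relatedness is taken
    from the manifest's family assignment. Output is sorted by gene symbol
    and invariant under permutation of the input order.

    With ``require_unrelated_carriers=False`` the looser reading applies:
    any gene with two or more qualifying variant observations counts,
    even within a single individual.
    """
    by_gene: Dict[str, List[FilteredVariant]] = defaultdict(list)
    for fv in records:
        manifest.family_of(fv.sample_id)  # raises for unknown samples
        by_gene[fv.gene].append(fv)

    out: List[RecurrenceRecord] = []
    for gene in sorted(by_gene):
        variants = sorted(
            by_gene[gene], key=lambda fv: (fv.variant_key, fv.sample_id)
        )
        carriers = sorted({fv.sample_id for fv in variants})
        families = tuple(manifest.family_of(s) for s in carriers)
        recurrent = (
            len(set(families)) >= 2
            if require_unrelated_carriers
            else len(variants) >= 2
        )
        if recurrent:
            out.append(
                RecurrenceRecord(
                    gene_symbol=gene,
                    carrier_sample_ids=tuple(carriers),
                    carrier_family_ids=families,
                    variants=tuple(variants),
                )
            )
    return out
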