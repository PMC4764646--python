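"""Call-level filter cascade for germline rare-variant discovery.

Four gates are applied in a fixed order to every sample-variant observation:

1. **Quality** — read depth >= 10, variant reads >= 5, unique starts >= 5
   (substitutions only; the field is absent for indels and the rule is then
   skipped), variant-read fraction >= 28%.
2. **Population frequency** — minor allele frequency <= 0.001 in every
   enforced reference panel. A per-panel override allows the strict
   "absent from panel" reading (max MAF 0) for an in-house database.
3. **Loss-of-function-tolerant gene exclusion** — genes known to tolerate
   truncating variation in healthy populations are removed.
4. **Impact classification** — protein-truncating consequences (nonsense,
   frameshift, canonical splice site) are kept regardless of conservation;
   missense changes are kept only at strongly conserved positions
   (PhyloP >= 3.0); everything else is excluded.

All thresholds are inclusive; ties are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .model import (
    FilteredVariant,
    GeneListPack,
    ReferencePanelCounts,
    TRUNCATING_CONSEQUENCES,
    VariantCall,
    VariantRecord,
)

logger = logging.getLogger(__name__)

IMPACT_TRUNCATING = "truncating"
IMPACT_CONSERVED_MISSENSE = "conserved_missense"
IMPACT_EXCLUDED = "excluded"


class FilterError(ValueError):
    """Raised when a filter cannot be evaluated (e.g. missing panel)."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the filter cascade (all inclusive).

    ``frequency_panels`` names the reference panels whose MAF must be at or
    below ``max_panel_maf``; ``panel_max_maf`` overrides the cutoff per panel
    (0.0 reproduces a strict absence requirement).
    """

    min_total_reads: int = 10
    min_variant_reads: int = 5
    min_unique_starts: int = 5
    min_variant_fraction: float = 0.28
    max_panel_maf: float = 0.001
    phylop_min: float = 3.0
    frequency_panels: Tuple[str, ...] = ("inhouse", "evs")
    panel_max_maf: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.min_variant_fraction <= 1:
            raise ValueError("min_variant_fraction must be in (0, 1]")
        for name in ("min_total_reads", "min_variant_reads", "min_unique_starts",
                     "max_panel_maf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "frequency_panels", tuple(self.frequency_panels))
        object.__setattr__(self, "panel_max_maf", dict(self.panel_max_maf))

    def maf_cutoff(self, panel_id: str) -> float:
        return self.panel_max_maf.get(panel_id, self.max_panel_maf)

    def fingerprint(self) -> str:
        """Stable digest of all thresholds.

        Case and control cohorts must be filtered identically before any
        burden comparison; the screen enforces equality of this digest.
        """
        payload = {
            "min_total_reads": self.min_total_reads,
            "min_variant_reads": self.min_variant_reads,
            "min_unique_starts": self.min_unique_starts,
            "min_variant_fraction": self.min_variant_fraction,
            "max_panel_maf": self.max_panel_maf,
            "phylop_min": self.phylop_min,
            "frequency_panels": list(self.frequency_panels),
            "panel_max_maf": dict(sorted(self.panel_max_maf.items())),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class FilterOutcome:
    """Verdict for one record: retained flag, impact class, failed rules."""

    retained: bool
    impact_class: str
    failed_rules: Tuple[str, ...]


@dataclass
class FilterResult:
    """Cascade output: retained records, per-sample summary, provenance."""

    retained: List[FilteredVariant]
    summary: pd.DataFrame  # sample_id, n_truncating, n_conserved_missense
    config_fingerprint: str
    funnel: Dict[str, int]


def passes_quality(call: VariantCall, config: FilterConfig) -> Tuple[bool, List[str]]:
    """Evaluate the read-level quality gate.

    Returns the verdict and the identifiers of any failed rules. The
    unique-starts rule is skipped when the field is absent (indels carry no
    unique-starts count).
    """
    failed: List[str] = []
    if call.total_reads < config.min_total_reads:
        failed.append("min_total_reads")
    if call.variant_reads < config.min_variant_reads:
        failed.append("min_variant_reads")
    if call.unique_starts is not None and call.unique_starts < config.min_unique_starts:
        failed.append("min_unique_starts")
    if call.variant_read_fraction < config.min_variant_fraction:
        failed.append("min_variant_fraction")
    return (not failed, failed)


def passes_frequency(
    panels: Mapping[str, ReferencePanelCounts], config: FilterConfig
) -> bool:
    """True iff the MAF is at or below the cutoff in every enforced panel.

    A panel named in ``config.frequency_panels`` but missing from the record
    is an error: silently treating missing counts as zero would let common
    variants through.
    """
    for panel_id in config.frequency_panels:
        counts = panels.get(panel_id)
        if counts is None:
            raise FilterError(
                f"enforced reference panel {panel_id!r} missing from record"
            )
        if counts.maf > config.maf_cutoff(panel_id):
            return False
    return True


def classify_impact(annotation, config: FilterConfig) -> str:
    """Assign the impact class used throughout the downstream analysis.

    Truncating consequences qualify regardless of conservation (the
    canonical-splice example in the discovery set has PhyloP 2.427 and is
    retained). Missense changes qualify only with PhyloP >= ``phylop_min``;
    a missense record with no PhyloP value cannot be classified and is
    excluded with a warning.
    """
    if annotation.consequence in TRUNCATING_CONSEQUENCES:
        return IMPACT_TRUNCATING
    if annotation.consequence == "missense":
        if annotation.phylop is None:
            logger.warning(
                "missense variant %s %s has no PhyloP score; excluded",
                annotation.gene_symbol, annotation.protein_change or annotation.cdna_change,
            )
            return IMPACT_EXCLUDED
        if annotation.phylop >= config.phylop_min:
            return IMPACT_CONSERVED_MISSENSE
    return IMPACT_EXCLUDED


def evaluate_record(record: VariantRecord, config: FilterConfig) -> FilterOutcome:
    """Full per-record verdict across quality, frequency and impact gates."""
    _, failed = passes_quality(record.call, config)
    failed = list(failed)
    if not passes_frequency(record.panels, config):
        failed.append("max_panel_maf")
    impact = classify_impact(record.annotation, config)
    if impact == IMPACT_EXCLUDED:
        failed.append("impact_class")
    return FilterOutcome(retained=not failed, impact_class=impact, failed_rules=tuple(failed))


def exclude_lof_tolerant(
    records: Sequence[VariantRecord], lof_tolerant: Optional[GeneListPack]
) -> List[VariantRecord]:
    """Drop records in loss-of-function-tolerant genes; order preserved."""
    if lof_tolerant is None:
        return list(records)
    return [r for r in records if r.gene not in lof_tolerant]


def filter_cohort(
    records: Iterable[VariantRecord],
    config: FilterConfig,
    lof_tolerant: Optional[GeneListPack] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> FilterResult:
    """Run the full cascade over a cohort's observations.

    Gates compose in the fixed order quality -> frequency -> LoF-tolerant
    exclusion -> impact classification. The per-sample summary partitions the
    retained records into truncating and conserved-missense counts; samples
    listed in ``sample_ids`` appear in the summary even with zero survivors.
    """
    records = list(records)
    funnel: Dict[str, int] = {"input": len(records)}

    after_quality = [r for r in records if passes_quality(r.call, config)[0]]
    funnel["quality"] = len(after_quality)

    after_frequency = [r for r in after_quality if passes_frequency(r.panels, config)]
    funnel["frequency"] = len(after_frequency)

    after_lof = exclude_lof_tolerant(after_frequency, lof_tolerant)
    funnel["lof_tolerant"] = len(after_lof)

    retained: List[FilteredVariant] = []
    for r in after_lof:
        impact = classify_impact(r.annotation, config)
        if impact != IMPACT_EXCLUDED:
            retained.append(FilteredVariant(r, impact))
    funnel["impact"] = len(retained)

    counts: Dict[str, Dict[str, int]] = {}
    for sid in sample_ids or ():
        counts[sid] = {"n_truncating": 0, "n_conserved_missense": 0}
    for fv in retained:
        row = counts.setdefault(
            fv.sample_id, {"n_truncating": 0, "n_conserved_missense": 0}
        )
        key = "n_truncating" if fv.impact_class == IMPACT_TRUNCATING else "n_conserved_missense"
        row[key] += 1
    summary = pd.DataFrame(
        [
            {"sample_id": sid, **c}
            for sid, c in sorted(counts.items())
        ],
        columns=["sample_id", "n_truncating", "n_conserved_missense"],
    )
    return FilterResult(
        retained=retained,
        summary=summary,
        config_fingerprint=config.fingerprint(),
        funnel=funnel,
    )
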