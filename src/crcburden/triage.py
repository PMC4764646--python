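"""Known-gene annotation and four-step evidence triage of screen survivors.

Genes surviving the case-control burden screen are passed through four
ordered evidence filters, and each gene is reported at the first step it
matches:

1. recurrently affected by protein-truncating variants only
   (>= 2 truncating variants in carriers from distinct families);
2. member of the colorectal-cancer driver-gene list;
3. member of the mouse transposon-screen susceptibility list *and* of a
   cancer-related KEGG pathway;
4. member of the colorectal-cancer GWAS gene list.

Variants landing in known predisposition genes are annotated, never
auto-classified: establishing pathogenicity needs tumor and functional
evidence outside this package's inputs.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .burden import BurdenScreenResult, burden_results_frame
from .filtering import FilterConfig, IMPACT_TRUNCATING, classify_impact, passes_frequency, passes_quality
from .model import FilteredVariant, GeneListPack, VariantRecord
from .zygosity import RecurrenceRecord

TRIAGE_STEPS = (
    "step1_truncating_recurrent",
    "step2_driver",
    "step3_mouse_and_kegg",
    "step4_gwas",
)

_TRIAGE_PACKS = ("crc_driver", "mouse_transposon", "kegg_cancer_pathways", "gwas")
_KNOWN_PACKS = ("crc_predisposition", "cancer_syndrome")


class TriageError(ValueError):
    pass


@dataclass(frozen=True)
class KnownGeneHit:
    gene_symbol: str
    category: str  # which known-gene list matched
    variant: FilteredVariant
    interpretation_note: str = "requires functional follow-up; not auto-classified"


@dataclass(frozen=True)
class TriageResult:
    gene_symbol: str
    retained_at_step: str  # first matching step, or "none"
    matched_steps: Tuple[str, ...]  # all matching steps, for transparency
    supporting_variants: Tuple[FilteredVariant, ...]
    notes: str = ""


def annotate_known_genes(
    retained: Iterable[FilteredVariant], packs: Mapping[str, GeneListPack]
) -> List[KnownGeneHit]:
    """Flag retained variants that fall in known predisposition genes."""
    for pack_id in _KNOWN_PACKS:
        if pack_id not in packs:
            raise TriageError(f"missing gene-list pack {pack_id!r}")
    hits: List[KnownGeneHit] = []
    for fv in retained:
        for pack_id in _KNOWN_PACKS:  # CRC list takes precedence
            if fv.gene in packs[pack_id]:
                hits.append(KnownGeneHit(fv.gene, pack_id, fv))
                break
    hits.sort(key=lambda h: (h.gene_symbol, h.variant.variant_key, h.variant.sample_id))
    return hits


def _matched_steps(
    rec: RecurrenceRecord, packs: Mapping[str, GeneListPack]
) -> List[str]:
    steps: List[str] = []
    truncating = [v for v in rec.variants if v.impact_class == IMPACT_TRUNCATING]
    families = dict(zip(rec.carrier_sample_ids, rec.carrier_family_ids))
    truncating_families = {families[v.sample_id] for v in truncating}
    if (
        len(truncating) == len(rec.variants)
        and len(truncating) >= 2
        and len(truncating_families) >= 2
    ):
        steps.append("step1_truncating_recurrent")
    if rec.gene_symbol in packs["crc_driver"]:
        steps.append("step2_driver")
    if (
        rec.gene_symbol in packs["mouse_transposon"]
        and rec.gene_symbol in packs["kegg_cancer_pathways"]
    ):
        steps.append("step3_mouse_and_kegg")
    if rec.gene_symbol in packs["gwas"]:
        steps.append("step4_gwas")
    return steps


def triage_candidates(
    survivors: Sequence[RecurrenceRecord], packs: Mapping[str, GeneListPack]
) -> List[TriageResult]:
    """Apply the four ordered evidence steps to burden-screen survivors.

    Each gene is reported at the *first* matching step; all matching steps
    are also recorded so a multi-evidence gene is visible as such. Genes
    matching no step are reported with ``retained_at_step="none"``.
    """
    for pack_id in _TRIAGE_PACKS:
        if pack_id not in packs:
            raise TriageError(f"missing gene-list pack {pack_id!r}")
    results: List[TriageResult] = []
    for rec in sorted(survivors, key=lambda r: r.gene_symbol):
        steps = _matched_steps(rec, packs)
        results.append(
            TriageResult(
                gene_symbol=rec.gene_symbol,
                retained_at_step=steps[0] if steps else "none",
                matched_steps=tuple(steps),
                supporting_variants=rec.variants,
            )
        )
    return results


def select_replication_variants(
    records: Iterable[VariantRecord],
    config: Optional[FilterConfig] = None,
    apply_quality: bool = True,
) -> List[FilteredVariant]:
    """Select resequencing calls worth orthogonal validation.

    Applies the population-frequency rule (default: EVS MAF <= 0.001) and
    the impact rules (truncating, or missense with PhyloP >= 3.0). The
    read-level quality gate is platform-specific and can be disabled for
    amplicon data whose caller reports no unique starts.
    """
    if config is None:
        config = FilterConfig(frequency_panels=("evs",))
    selected: List[FilteredVariant] = []
    for record in records:
        if apply_quality and not passes_quality(record.call, config)[0]:
            continue
        if not passes_frequency(record.panels, config):
            continue
        impact = classify_impact(record.annotation, config)
        if impact == "excluded":
            continue
        selected.append(FilteredVariant(record, impact))
    return selected


# ---------------------------------------------------------------------------
# reporting


def _variant_row(fv: FilteredVariant) -> Dict[str, object]:
    call, ann = fv.record.call, fv.record.annotation
    return {
        "gene": fv.gene,
        "sample_id": call.sample_id,
        "chrom": call.chrom,
        "pos": call.pos,
        "ref": call.ref,
        "alt": call.alt,
        "cdna": ann.cdna_change,
        "prot": ann.protein_change,
        "csq": ann.consequence,
        "phylop": ann.phylop,
        "impact_class": fv.impact_class,
    }


def write_candidate_report(
    outdir,
    filter_summary=None,
    funnel: Optional[Mapping[str, int]] = None,
    biallelic: Optional[Mapping[str, Mapping[str, str]]] = None,
    recurrence: Optional[Sequence[RecurrenceRecord]] = None,
    burden: Optional[BurdenScreenResult] = None,
    known_hits: Optional[Sequence[KnownGeneHit]] = None,
    triage: Optional[Sequence[TriageResult]] = None,
    replication: Optional[Sequence[FilteredVariant]] = None,
) -> Dict[str, Path]:
    """Write machine- and human-readable reports for a pipeline run.

    Emits ``candidates.tsv`` (triaged genes with supporting variants),
    ``candidates.json`` (every section, machine readable) and
    ``summary.txt``. Ordering is deterministic (gene symbol, then
    position), so regenerating from identical inputs is byte-identical.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    triage = sorted(triage or [], key=lambda t: t.gene_symbol)
    rows = []
    for t in triage:
        for fv in sorted(t.supporting_variants, key=lambda v: (v.variant_key, v.sample_id)):
            rows.append({**_variant_row(fv), "retained_at_step": t.retained_at_step})
    tsv_path = outdir / "candidates.tsv"
    pd.DataFrame(
        rows,
        columns=[
            "gene", "retained_at_step", "sample_id", "chrom", "pos", "ref", "alt",
            "cdna", "prot", "csq", "phylop", "impact_class",
        ],
    ).to_csv(tsv_path, sep="\t", index=False)

    payload = {
        "funnel": dict(funnel or {}),
        "per_sample_summary": (
            filter_summary.to_dict(orient="records") if filter_summary is not None else []
        ),
        "biallelic_genes": {
            sample: dict(sorted(genes.items()))
            for sample, genes in sorted((biallelic or {}).items())
        },
        "recurrent_genes": [
            {
                "gene": r.gene_symbol,
                "n_variants": r.n_variants,
                "n_carriers": r.n_carriers,
                "n_unrelated_carriers": r.n_unrelated_carriers,
                "variants": [_variant_row(v) for v in r.variants],
            }
            for r in sorted(recurrence or [], key=lambda r: r.gene_symbol)
        ],
        "burden": (
            burden_results_frame(burden.results).to_dict(orient="records")
            if burden is not None
            else []
        ),
        "burden_removed": dict(sorted((burden.removed_genes if burden else {}).items())),
        "known_gene_hits": [
            {
                "gene": h.gene_symbol,
                "category": h.category,
                "note": h.interpretation_note,
                **_variant_row(h.variant),
            }
            for h in (known_hits or [])
        ],
        "triage": [
            {
                "gene": t.gene_symbol,
                "retained_at_step": t.retained_at_step,
                "matched_steps": list(t.matched_steps),
                "n_supporting_variants": len(t.supporting_variants),
                "notes": t.notes,
            }
            for t in triage
        ],
        "replication_variants": [
            _variant_row(v)
            for v in sorted(replication or [], key=lambda v: (v.variant_key, v.sample_id))
        ],
    }
    json_path = outdir / "candidates.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    lines = ["Candidate gene report", "=" * 21, ""]
    if funnel:
        lines.append("Filter funnel (records at each stage):")
        for stage, count in funnel.items():
            lines.append(f"  {stage}: {count}")
        lines.append("")
    if biallelic:
        lines.append("Biallelic candidate genes (per sample):")
        for sample, genes in sorted(biallelic.items()):
            for gene, mech in sorted(genes.items()):
                lines.append(f"  {sample}: {gene} ({mech})")
        lines.append("")
    lines.append(f"Recurrently affected genes: {len(payload['recurrent_genes'])}")
    if burden is not None:
        lines.append(
            f"Burden screen: {len(burden.retained_genes)} retained, "
            f"{len(burden.removed_genes)} removed"
        )
    lines.append(f"Known-gene hits: {len(payload['known_gene_hits'])}")
    lines.append("")
    lines.append("Triage:")
    for t in triage:
        lines.append(
            f"  {t.gene_symbol}: {t.retained_at_step}"
            + (f" (also {', '.join(t.matched_steps[1:])})" if len(t.matched_steps) > 1 else "")
        )
    if payload["replication_variants"]:
        lines.append("")
        lines.append(f"Replication variants selected: {len(payload['replication_variants'])}")
    summary_path = outdir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")

    return {"tsv": tsv_path, "json": json_path, "summary": summary_path}
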