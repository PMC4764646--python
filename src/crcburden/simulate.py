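"""Synthetic case/control cohort generator and screen calibration.

The generator emulates the statistical structure the analysis assumes:
per-individual, per-gene qualifying-variant counts are Poisson (rare-variant
regime, no linkage or haplotype structure), with a configurable relative
risk multiplying the case rate in *spiked* genes. Each emitted variant draws
read-level evidence, a consequence, a conservation score and reference-panel
allele counts so that every filter gate sees probability mass on both sides
of its threshold:

* PhyloP is a two-component mixture, uniform on [0, 3) and on [3, 7], so the
  conservation cutoff is exercised at both boundaries;
* panel allele counts place a configurable fraction of variants above
  MAF 0.001;
* read-level fields place a configurable fraction of variants just below one
  quality threshold, chosen uniformly among the four rules.

Ground truth (which gates each variant truly passes, which genes are truly
enriched) is recorded for every emitted variant, so filter correctness and
the burden screen's type-I error and power are measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .burden import burden_screen
from .filtering import FilterConfig, filter_cohort
from .model import (
    CohortSpec,
    ReferencePanelCounts,
    VariantAnnotation,
    VariantCall,
    VariantRecord,
)
from .zygosity import find_recurrent_genes

_BASES = ("A", "C", "G", "T")
_TRUNCATING_KINDS = ("nonsense", "frameshift", "canonical_splice")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    ``background_rate`` is the expected number of qualifying variants per
    gene across the whole case cohort; the per-individual Poisson rate is
    ``background_rate / n_case`` and applies to controls as well, so under
    the null both cohorts share one rate per gene. ``spiked_genes`` maps
    gene symbols (``GENE0007``-style indices into the simulated gene set)
    to a relative risk >= 1 multiplying the case rate only.
    """

    n_case: int = 55
    n_control: int = 164
    n_genes: int = 150
    background_rate: float = 0.5
    spiked_genes: Tuple[Tuple[str, float], ...] = ()
    fraction_truncating: float = 0.15
    fraction_synonymous: float = 0.08
    phylop_above_fraction: float = 0.65
    panel_common_fraction: float = 0.12
    quality_fail_fraction: float = 0.10
    fraction_homozygous: float = 0.02
    families: Optional[Mapping[str, str]] = None
    panels: Tuple[Tuple[str, int], ...] = (("inhouse", 2037), ("evs", 6503))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_truncating", "fraction_synonymous", "phylop_above_fraction",
            "panel_common_fraction", "quality_fail_fraction", "fraction_homozygous",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.fraction_truncating + self.fraction_synonymous > 1:
            raise SimulationError("consequence fractions exceed 1")
        if self.background_rate < 0:
            raise SimulationError("background_rate must be >= 0")
        for gene, rr in self.spiked_genes:
            if rr < 1:
                raise SimulationError(f"relative risk for {gene} must be >= 1")
        object.__setattr__(self, "spiked_genes", tuple(self.spiked_genes))
        object.__setattr__(self, "panels", tuple(self.panels))

    def gene_symbols(self) -> List[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class VariantTruth:
    """Which gates a simulated variant truly passes, by construction."""

    quality_pass: bool
    frequency_pass: bool
    impact_pass: bool
    impact_class: str  # intended class when impact_pass, else "excluded"

    @property
    def passes_all(self) -> bool:
        return self.quality_pass and self.frequency_pass and self.impact_pass


@dataclass
class SimulationTruth:
    enriched_genes: Dict[str, float]  # gene -> relative risk (spiked only)
    variants: Dict[Tuple[str, str, int, str, str], VariantTruth]

    def truth_of(self, record: VariantRecord) -> VariantTruth:
        call = record.call
        return self.variants[(call.sample_id, call.chrom, call.pos, call.ref, call.alt)]


@dataclass
class SimulatedData:
    case_records: List[VariantRecord]
    control_records: List[VariantRecord]
    case_cohort: CohortSpec
    control_cohort: CohortSpec
    truth: SimulationTruth


def _draw_quality(
    rng: np.random.Generator, is_indel: bool, homozygous: bool, fail: bool
) -> Tuple[int, int, Optional[int], bool]:
    """Read-level fields for one variant; returns (dp, vr, us, quality_pass)."""
    if not fail:
        dp = int(rng.integers(20, 101))
        if homozygous:
            vr = math.ceil(0.97 * dp)
        else:
            vr = int(rng.integers(math.ceil(0.35 * dp), math.floor(0.65 * dp) + 1))
        vr = max(5, min(vr, dp))
        us = None if is_indel else int(rng.integers(5, 21))
        return dp, vr, us, True
    # place the variant just below one threshold, chosen uniformly
    rules = ["depth", "variant_reads", "fraction"] + ([] if is_indel else ["unique_starts"])
    rule = rules[int(rng.integers(len(rules)))]
    if rule == "depth":
        dp = int(rng.integers(1, 10))
        vr = dp
        us = None if is_indel else int(rng.integers(5, 21))
    elif rule == "variant_reads":
        dp = int(rng.integers(20, 41))
        vr = int(rng.integers(0, 5))
        us = None if is_indel else int(rng.integers(5, 21))
    elif rule == "unique_starts":
        dp = int(rng.integers(20, 41))
        vr = int(rng.integers(math.ceil(0.35 * dp), math.floor(0.65 * dp) + 1))
        us = int(rng.integers(0, 5))
    else:  # fraction just below 28%
        dp = int(rng.integers(40, 101))
        vr = max(5, math.floor(0.27 * dp))
        us = None if is_indel else int(rng.integers(5, 21))
    return dp, min(vr, dp), us, False


def _draw_panels(
    rng: np.random.Generator, panels: Sequence[Tuple[str, int]], common: bool
) -> Tuple[Dict[str, ReferencePanelCounts], bool]:
    """Panel allele counts; ``common`` pushes one panel above MAF 0.001."""
    out: Dict[str, ReferencePanelCounts] = {}
    hot = int(rng.integers(len(panels))) if common else -1
    frequency_pass = True
    for i, (panel_id, n_ind) in enumerate(panels):
        if i == hot:
            low = math.floor(0.001 * 2 * n_ind) + 1  # smallest count above the cutoff
            ac = int(rng.integers(low, min(4 * low, 2 * n_ind) + 1))
            frequency_pass = False
        else:
            ac = int(rng.integers(0, 2))  # 0 or 1: rare in every realistic panel
        out[panel_id] = ReferencePanelCounts(panel_id, n_ind, ac)
    return out, frequency_pass


def _draw_variant(
    rng: np.random.Generator,
    config: SimulationConfig,
    sample_id: str,
    gene: str,
    gene_index: int,
    slot: int,
) -> Tuple[VariantRecord, VariantTruth]:
    u = rng.random()
    if u < config.fraction_truncating:
        consequence = _TRUNCATING_KINDS[int(rng.integers(3))]
    elif u < config.fraction_truncating + config.fraction_synonymous:
        consequence = "synonymous"
    else:
        consequence = "missense"
    is_indel = consequence == "frameshift"

    phylop: Optional[float]
    if consequence == "missense":
        if rng.random() < config.phylop_above_fraction:
            phylop = float(3.0 + 4.0 * rng.random())
        else:
            phylop = float(3.0 * rng.random())
    else:
        phylop = float(7.0 * rng.random())

    if consequence in _TRUNCATING_KINDS:
        impact_class, impact_pass = "truncating", True
    elif consequence == "missense" and phylop >= 3.0:
        impact_class, impact_pass = "conserved_missense", True
    else:
        impact_class, impact_pass = "excluded", False

    homozygous = rng.random() < config.fraction_homozygous
    dp, vr, us, quality_pass = _draw_quality(
        rng, is_indel, homozygous, fail=rng.random() < config.quality_fail_fraction
    )
    panels, frequency_pass = _draw_panels(
        rng, config.panels, common=rng.random() < config.panel_common_fraction
    )

    chrom = str(gene_index % 22 + 1)
    pos = 1_000_000 * (gene_index + 1) + slot
    ref = _BASES[int(rng.integers(4))]
    alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
    if is_indel:
        alt = ref + alt  # an insertion, so unique starts are undefined

    record = VariantRecord(
        call=VariantCall(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            total_reads=dp, variant_reads=vr, unique_starts=us,
        ),
        annotation=VariantAnnotation(
            gene_symbol=gene,
            transcript=f"NM_{900000 + gene_index}",
            cdna_change=f"c.{slot + 1}{ref}>{alt[-1]}",
            protein_change="",
            consequence=consequence,
            phylop=phylop,
        ),
        panels=panels,
    )
    truth = VariantTruth(
        quality_pass=quality_pass,
        frequency_pass=frequency_pass,
        impact_pass=impact_pass,
        impact_class=impact_class if impact_pass else "excluded",
    )
    return record, truth


def simulate_cohort(config: SimulationConfig) -> SimulatedData:
    """Generate case and control cohorts with ground truth.

    Identical configuration (including seed) yields identical output. The
    emitted tables are valid input for the TSV reader and the filter
    cascade; per-gene spike relative risks scale the case rate only.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes = config.gene_symbols()
    rr = dict(config.spiked_genes)
    unknown = set(rr) - set(genes)
    if unknown:
        raise SimulationError(f"spiked genes not in simulated gene set: {sorted(unknown)}")

    rate = config.background_rate / config.n_case  # per individual per gene

    case_samples = [f"S{i + 1:04d}" for i in range(config.n_case)]
    control_samples = [f"C{i + 1:04d}" for i in range(config.n_control)]
    if config.families:
        case_families = {s: config.families.get(s, f"F_{s}") for s in case_samples}
    else:
        case_families = {s: f"F_{s}" for s in case_samples}
    case_cohort = CohortSpec("discovery", "discovery", case_families)
    control_cohort = CohortSpec(
        "control1", "control", {s: f"F_{s}" for s in control_samples}
    )

    truth = SimulationTruth(enriched_genes=dict(rr), variants={})
    slot_counters = [0] * config.n_genes

    def emit(samples: List[str], is_case: bool) -> List[VariantRecord]:
        records: List[VariantRecord] = []
        # one Poisson matrix per cohort keeps the draw order deterministic
        rates = np.full((len(samples), config.n_genes), rate)
        if is_case:
            for gene, risk in rr.items():
                rates[:, genes.index(gene)] *= risk
        counts = rng.poisson(rates)
        for si, sample in enumerate(samples):
            for gi in np.nonzero(counts[si])[0]:
                for _ in range(int(counts[si, gi])):
                    slot_counters[gi] += 1
                    record, vt = _draw_variant(
                        rng, config, sample, genes[gi], int(gi), slot_counters[gi]
                    )
                    call = record.call
                    truth.variants[
                        (call.sample_id, call.chrom, call.pos, call.ref, call.alt)
                    ] = vt
                    records.append(record)
        return records

    case_records = emit(case_samples, is_case=True)
    control_records = emit(control_samples, is_case=False)
    return SimulatedData(
        case_records=case_records,
        control_records=control_records,
        case_cohort=case_cohort,
        control_cohort=control_cohort,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# calibration of the burden screen


@dataclass
class CalibrationResult:
    """Empirical operating characteristics of the burden screen.

    Rates are conditioned on genes that reach the test (recurrent with at
    least one pooled qualifying variant). ``type1_exceeds_alpha`` flags a
    type-I rate more than three Monte-Carlo standard errors above the
    nominal level; the chi-square reference is approximate on small
    discrete counts, so the rate is reported, not assumed.
    """

    alpha: float
    n_reps: int
    type1_rate: float
    type1_se: float
    n_null_tests: int
    power: Optional[float]
    power_se: Optional[float]
    n_spiked_tests: int
    type1_exceeds_alpha: bool
    #: Detection rates: rejection per gene per replicate, counting a gene
    #: that never reaches the test as not detected. Unlike the conditional
    #: rates these are comparable across configurations, because the
    #: conditioning set (recurrent genes) itself grows with the relative
    #: risk and with the null selection effect.
    detection_power: Optional[float] = None
    detection_power_se: Optional[float] = None
    null_detection_rate: Optional[float] = None


def _rate_and_se(rejections: int, n: int) -> Tuple[float, float]:
    if n == 0:
        return float("nan"), float("nan")
    rate = rejections / n
    return rate, math.sqrt(max(rate * (1 - rate), 1e-12) / n)


def estimate_calibration(
    config: SimulationConfig,
    n_reps: int = 200,
    alpha: float = 0.05,
    filter_config: Optional[FilterConfig] = None,
) -> CalibrationResult:
    """Monte-Carlo type-I error and power of the full screen.

    Each replicate runs the real pipeline: simulate both cohorts, filter
    them under one configuration, find recurrent genes in the cases, and
    screen them against the controls. A *rejection* is a recurrent gene
    with chi-square p <= alpha. Null and spiked genes are tallied
    separately; replicate seeds derive deterministically from
    ``config.seed``, so two configs sharing a seed share random numbers
    (common-random-number power comparisons).
    """
    if filter_config is None:
        filter_config = FilterConfig(
            frequency_panels=tuple(p for p, _ in config.panels)
        )
    spiked = {g for g, _ in config.spiked_genes}
    null_tests = null_rej = spiked_tests = spiked_rej = 0
    for rep in range(n_reps):
        rep_config = SimulationConfig(
            **{**_config_kwargs(config), "seed": _rep_seed(config.seed, rep)}
        )
        data = simulate_cohort(rep_config)
        case_filtered = filter_cohort(data.case_records, filter_config)
        control_filtered = filter_cohort(data.control_records, filter_config)
        recurrence = find_recurrent_genes(case_filtered.retained, data.case_cohort)
        if not recurrence:
            continue
        screen = burden_screen(
            recurrence,
            n_case=config.n_case,
            control_variants=control_filtered.retained,
            n_control=config.n_control,
            alpha=alpha,
            case_fingerprint=case_filtered.config_fingerprint,
            control_fingerprint=control_filtered.config_fingerprint,
        )
        for res in screen.results:
            if res.gene_symbol in spiked:
                spiked_tests += 1
                spiked_rej += res.p_value <= alpha
            else:
                null_tests += 1
                null_rej += res.p_value <= alpha

    type1, type1_se = _rate_and_se(null_rej, null_tests)
    if spiked_tests:
        power, power_se = _rate_and_se(spiked_rej, spiked_tests)
    else:
        power = power_se = None
    exceeds = bool(null_tests and type1 > alpha + 3 * type1_se)

    n_spiked_total = len(spiked) * n_reps
    n_null_total = (config.n_genes - len(spiked)) * n_reps
    if n_spiked_total:
        det_power, det_power_se = _rate_and_se(spiked_rej, n_spiked_total)
    else:
        det_power = det_power_se = None
    null_det = null_rej / n_null_total if n_null_total else None
    return CalibrationResult(
        alpha=alpha,
        n_reps=n_reps,
        type1_rate=type1,
        type1_se=type1_se,
        n_null_tests=null_tests,
        power=power,
        power_se=power_se,
        n_spiked_tests=spiked_tests,
        type1_exceeds_alpha=exceeds,
        detection_power=det_power,
        detection_power_se=det_power_se,
        null_detection_rate=null_det,
    )


def _config_kwargs(config: SimulationConfig) -> Dict[str, object]:
    return {
        "n_case": config.n_case,
        "n_control": config.n_control,
        "n_genes": config.n_genes,
        "background_rate": config.background_rate,
        "spiked_genes": config.spiked_genes,
        "fraction_truncating": config.fraction_truncating,
        "fraction_synonymous": config.fraction_synonymous,
        "phylop_above_fraction": config.phylop_above_fraction,
        "panel_common_fraction": config.panel_common_fraction,
        "quality_fail_fraction": config.quality_fail_fraction,
        "fraction_homozygous": config.fraction_homozygous,
        "families": config.families,
        "panels": config.panels,
        "seed": config.seed,
    }


def _rep_seed(seed: int, rep: int) -> int:
    # derived, stable, and independent of how many replicates precede a rep
    return int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))
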