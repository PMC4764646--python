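"""Case-vs-control statistical screen for recurrently affected genes.

Per gene, qualifying-variant counts in the case cohort are compared with a
control cohort processed through the identical filter cascade, using a
chi-square goodness-of-fit test: under the null, the pooled count splits
between cohorts in proportion to the number of individuals sequenced. The
family of per-gene p-values is corrected with the Benjamini-Hochberg
step-up procedure; genes are retained for downstream triage at raw
p <= 0.05, with the FDR flags reported alongside.

A Fisher's exact test on carrier counts (two-sided, minimum-likelihood
convention) serves as the exact comparison against high-coverage control
panels in the replication stage.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .model import FilteredVariant
from .zygosity import RecurrenceRecord

BURDEN_UNIT_VARIANTS = "variants"
BURDEN_UNIT_CARRIERS = "carriers"


class BurdenError(ValueError):
    """Raised for undefined tests or non-comparable inputs."""


@dataclass(frozen=True)
class GeneBurdenResult:
    gene_symbol: str
    case_count: int
    n_case: int
    control_count: int
    n_control: int
    chi2_stat: float
    p_value: float
    bh_critical: float
    adjusted_p: float
    significant_raw: bool
    significant_bh: bool


@dataclass(frozen=True)
class FisherResult:
    gene_symbol: str
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float


@dataclass(frozen=True)
class BHItem:
    p_value: float
    bh_critical: float
    adjusted_p: float
    significant: bool


def chi2_burden(
    case_count: int, n_case: int, control_count: int, n_control: int
) -> Tuple[float, float]:
    """Chi-square goodness-of-fit burden test on pooled counts.

    Expected counts are proportional to cohort sizes:
    ``E_case = T * n_case / (n_case + n_control)`` with ``T`` the pooled
    count. The statistic is Pearson's ``sum((O - E)^2 / E)`` referred to a
    chi-square distribution with 1 degree of freedom, no continuity
    correction.
    """
    if n_case <= 0 or n_control <= 0:
        raise BurdenError("cohort sizes must be positive")
    if case_count < 0 or control_count < 0:
        raise BurdenError("counts must be non-negative")
    total = case_count + control_count
    if total == 0:
        raise BurdenError("no qualifying variants: test undefined")
    e_case = total * n_case / (n_case + n_control)
    e_ctrl = total - e_case
    stat = (case_count - e_case) ** 2 / e_case + (control_count - e_ctrl) ** 2 / e_ctrl
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def benjamini_hochberg(
    p_values: Sequence[float], alpha: float = 0.05, m: Optional[int] = None
) -> List[BHItem]:
    """Benjamini-Hochberg step-up procedure.

    ``m`` is the number of tests corrected over; it may exceed the number of
    supplied p-values (e.g. correcting over every recurrent gene while only
    some were carried forward). Critical value for ascending rank ``i`` is
    ``(i / m) * alpha``; the significant set is every rank at or below the
    largest ``i`` with ``p_(i) <= (i/m) * alpha``. Adjusted p-values follow
    the standard step-up definition ``min_{j >= i} (m / j) * p_(j)``,
    capped at 1. Output preserves input order.
    """
    p = list(p_values)
    if any(not 0 <= x <= 1 for x in p):
        raise BurdenError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise BurdenError("alpha must be in (0, 1)")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise BurdenError(f"m ({m}) must be >= number of p-values ({n})")
    if n == 0:
        return []

    order = sorted(range(n), key=lambda i: p[i])
    rank_of = [0] * n
    criticals = [0.0] * n
    adjusted = [0.0] * n
    max_sig_rank = 0
    for rank, idx in enumerate(order, start=1):
        rank_of[idx] = rank
        criticals[idx] = rank / m * alpha
        if p[idx] <= criticals[idx]:
            max_sig_rank = rank
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m / rank * p[idx])
        adjusted[idx] = running_min
    return [
        BHItem(
            p_value=p[i],
            bh_critical=criticals[i],
            adjusted_p=adjusted[i],
            significant=rank_of[i] <= max_sig_rank,
        )
        for i in range(n)
    ]


def fisher_exact_carriers(
    case_carriers: int, n_case: int, control_carriers: int, n_control: int,
    gene_symbol: str = "",
) -> FisherResult:
    """Two-sided Fisher's exact test on a carrier 2x2 table.

    The table is carriers / non-carriers by case / control; the two-sided
    p-value sums all hypergeometric outcomes no more probable than the
    observed table (minimum-likelihood convention). The odds ratio is the
    sample odds ratio, infinite when a zero cell makes it unbounded.
    """
    if not 0 <= case_carriers <= n_case or not 0 <= control_carriers <= n_control:
        raise BurdenError("carrier counts must not exceed cohort sizes")
    table = [
        [case_carriers, n_case - case_carriers],
        [control_carriers, n_control - control_carriers],
    ]
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherResult(
        gene_symbol=gene_symbol,
        table=((table[0][0], table[0][1]), (table[1][0], table[1][1])),
        odds_ratio=float(odds_ratio),
        p_value=float(p),
    )


def count_gene_burden(
    variants: Iterable[FilteredVariant], unit: str = BURDEN_UNIT_VARIANTS
) -> Dict[str, int]:
    """Per-gene qualifying burden in the requested unit.

    ``variants`` counts sample-variant observations; ``carriers`` counts
    distinct samples carrying at least one qualifying variant.
    """
    if unit == BURDEN_UNIT_VARIANTS:
        counts: Dict[str, int] = defaultdict(int)
        for fv in variants:
            counts[fv.gene] += 1
        return dict(counts)
    if unit == BURDEN_UNIT_CARRIERS:
        carriers: Dict[str, set] = defaultdict(set)
        for fv in variants:
            carriers[fv.gene].add(fv.sample_id)
        return {g: len(s) for g, s in carriers.items()}
    raise BurdenError(f"unknown burden unit {unit!r}")


@dataclass
class BurdenScreenResult:
    results: List[GeneBurdenResult]
    retained_genes: List[str]
    removed_genes: Dict[str, str]  # gene -> reason


def burden_screen(
    recurrence: Sequence[RecurrenceRecord],
    n_case: int,
    control_variants: Sequence[FilteredVariant],
    n_control: int,
    alpha: float = 0.05,
    m: Optional[int] = None,
    unit: str = BURDEN_UNIT_VARIANTS,
    case_fingerprint: Optional[str] = None,
    control_fingerprint: Optional[str] = None,
) -> BurdenScreenResult:
    """Screen recurrent genes for case-vs-control burden enrichment.

    One chi-square result per recurrent gene, BH-corrected over ``m`` tests
    (default: the number of recurrent genes). Retention for triage uses raw
    p <= ``alpha``; the BH flag is reported alongside so an all-null FDR
    outcome still leaves the nominally enriched genes available, mirroring
    a screen-then-triage design.

    When fingerprints are supplied they must match: a control cohort
    filtered under different thresholds is not a valid comparator.
    """
    if case_fingerprint is not None and control_fingerprint is not None:
        if case_fingerprint != control_fingerprint:
            raise BurdenError(
                "filter-config fingerprint mismatch between case "
                f"({case_fingerprint}) and control ({control_fingerprint}) cohorts"
            )
    if m is None:
        m = len(recurrence)

    control_counts = count_gene_burden(control_variants, unit=unit)
    genes, case_counts, ctrl_counts, stats_p = [], [], [], []
    for rec in recurrence:
        if unit == BURDEN_UNIT_VARIANTS:
            case_n = rec.n_variants
        else:
            case_n = rec.n_carriers
        ctrl_n = control_counts.get(rec.gene_symbol, 0)
        stat, p = chi2_burden(case_n, n_case, ctrl_n, n_control)
        genes.append(rec.gene_symbol)
        case_counts.append(case_n)
        ctrl_counts.append(ctrl_n)
        stats_p.append((stat, p))

    bh = benjamini_hochberg([p for _, p in stats_p], alpha=alpha, m=m) if genes else []
    results: List[GeneBurdenResult] = []
    retained: List[str] = []
    removed: Dict[str, str] = {}
    for gene, case_n, ctrl_n, (stat, p), item in zip(
        genes, case_counts, ctrl_counts, stats_p, bh
    ):
        res = GeneBurdenResult(
            gene_symbol=gene,
            case_count=case_n,
            n_case=n_case,
            control_count=ctrl_n,
            n_control=n_control,
            chi2_stat=stat,
            p_value=p,
            bh_critical=item.bh_critical,
            adjusted_p=item.adjusted_p,
            significant_raw=p <= alpha,
            significant_bh=item.significant,
        )
        results.append(res)
        if res.significant_raw and case_n / n_case > ctrl_n / n_control:
            retained.append(gene)
        elif not res.significant_raw:
            removed[gene] = f"chi2 p={p:.4g} > {alpha}"
        else:
            removed[gene] = "burden higher in controls"
    return BurdenScreenResult(results=results, retained_genes=retained, removed_genes=removed)


def burden_results_frame(results: Sequence[GeneBurdenResult]):
    """Burden results as a DataFrame matching the emitted TSV layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": r.gene_symbol,
                "case_count": r.case_count,
                "control_count": r.control_count,
                "chi2": r.chi2_stat,
                "p": r.p_value,
                "bh_critical": r.bh_critical,
                "adjusted_p": r.adjusted_p,
                "significant_raw": r.significant_raw,
                "significant_bh": r.significant_bh,
            }
            for r in results
        ],
        columns=[
            "gene", "case_count", "control_count", "chi2", "p",
            "bh_critical", "adjusted_p", "significant_raw", "significant_bh",
        ],
    )
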