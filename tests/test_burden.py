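"""Burden statistics against independent oracles.

The chi-square oracle is the closed form ``sf(x; df=1) = erfc(sqrt(x/2))``
from the standard library; the Fisher oracle enumerates the hypergeometric
support with exact integer binomials. Both are independent of the
implementation paths they check.
"""

import math
import random

import pytest

from crcburden.burden import (
    BurdenError,
    benjamini_hochberg,
    burden_screen,
    chi2_burden,
    count_gene_burden,
    fisher_exact_carriers,
)
from crcburden.filtering import IMPACT_CONSERVED_MISSENSE
from crcburden.model import CohortSpec, FilteredVariant
from crcburden.zygosity import find_recurrent_genes

from conftest import make_record


def chi2_sf_oracle(x: float) -> float:
    """Survival function of chi-square with 1 df, closed form."""
    return math.erfc(math.sqrt(x / 2.0))


def fisher_oracle(a: int, n1: int, b: int, n2: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    X = case carriers given K = a + b total carriers drawn from n1 + n2;
    sums P(X = x) over all x whose probability does not exceed the observed
    table's (minimum-likelihood convention, with the customary 1 + 1e-7
    floating-point tie guard).
    """
    K, N = a + b, n1 + n2
    denom = math.comb(N, K)
    pmf = {
        x: math.comb(n1, x) * math.comb(n2, K - x) / denom
        for x in range(max(0, K - n2), min(K, n1) + 1)
    }
    cutoff = pmf[a] * (1 + 1e-7)
    return min(1.0, sum(p for p in pmf.values() if p <= cutoff))


class TestChi2Burden:
    def test_case_only_burden_hand_computed(self):
        """3 case variants vs 0 control variants, 55 vs 164 individuals."""
        stat, p = chi2_burden(3, 55, 0, 164)
        e_case = 3 * 55 / 219
        e_ctrl = 3 - e_case
        expected_stat = (3 - e_case) ** 2 / e_case + e_ctrl
        assert stat == pytest.approx(expected_stat)
        assert stat == pytest.approx(8.95, abs=0.01)
        assert p == pytest.approx(chi2_sf_oracle(expected_stat), abs=1e-12)
        assert p == pytest.approx(0.0028, abs=2e-4)

    def test_proportional_burden_is_null(self):
        """5 vs 15 splits almost exactly as 55 : 164 — no signal."""
        stat, p = chi2_burden(5, 55, 15, 164)
        assert stat == pytest.approx(0.00014, abs=5e-5)
        assert p > 0.98

    def test_no_variants_is_undefined(self):
        with pytest.raises(BurdenError, match="no qualifying variants"):
            chi2_burden(0, 55, 0, 164)

    def test_matches_independent_cdf_oracle_on_random_configs(self):
        """1,000 random count configurations agree with erfc to 1e-10."""
        rng = random.Random(20240917)
        for _ in range(1000):
            n1, n2 = rng.randint(10, 500), rng.randint(10, 5000)
            a, b = rng.randint(0, 40), rng.randint(0, 40)
            if a + b == 0:
                a = 1
            stat, p = chi2_burden(a, n1, b, n2)
            assert abs(p - chi2_sf_oracle(stat)) < 1e-10


class TestFisher:
    def test_two_carriers_vs_none_enumerated(self):
        # P(X=2) = (55*54)/(219*218) with both less-extreme outcomes larger
        res = fisher_exact_carriers(2, 55, 0, 164)
        assert res.p_value == pytest.approx(55 * 54 / (219 * 218), rel=1e-9)
        assert res.p_value == pytest.approx(0.0622, abs=1e-4)
        assert math.isinf(res.odds_ratio)

    def test_empty_table_p_is_one(self):
        assert fisher_exact_carriers(0, 55, 0, 164).p_value == 1.0

    def test_symmetric_under_column_swap(self):
        p1 = fisher_exact_carriers(3, 55, 4, 164).p_value
        p2 = fisher_exact_carriers(4, 164, 3, 55).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_carriers_cannot_exceed_cohort(self):
        with pytest.raises(BurdenError):
            fisher_exact_carriers(56, 55, 0, 164)

    def test_exhaustive_agreement_small_margins(self):
        """Every table with both margins <= 12 matches exact enumeration."""
        for n1 in range(1, 13):
            for n2 in range(1, 13):
                for K in range(0, n1 + n2 + 1):
                    for a in range(max(0, K - n2), min(K, n1) + 1):
                        p = fisher_exact_carriers(a, n1, K - a, n2).p_value
                        assert p == pytest.approx(
                            fisher_oracle(a, n1, K - a, n2), rel=1e-9, abs=1e-12
                        ), (a, n1, K - a, n2)

    def test_randomized_agreement_margins_to_60(self):
        """Seeded random tables with margins up to 60 match enumeration."""
        rng = random.Random(7)
        for _ in range(400):
            n1, n2 = rng.randint(1, 60), rng.randint(1, 60)
            a, b = rng.randint(0, n1), rng.randint(0, n2)
            p = fisher_exact_carriers(a, n1, b, n2).p_value
            assert p == pytest.approx(fisher_oracle(a, n1, b, n2), rel=1e-9, abs=1e-12)

    def test_fisher_chi2_converge_at_scale(self):
        """At fixed proportions the exact and asymptotic p-values approach."""
        def reldiff(k):
            pf = fisher_exact_carriers(3 * k, 55 * k, 6 * k, 164 * k).p_value
            _, pc = chi2_burden(3 * k, 55 * k, 6 * k, 164 * k)
            return abs(pf - pc) / pc

        assert reldiff(20) < reldiff(1)


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        """criticals 0.0125/0.025/0.0375/0.05 -> first two significant."""
        items = benjamini_hochberg([0.001, 0.02, 0.04, 0.9], alpha=0.05, m=4)
        assert [i.significant for i in items] == [True, True, False, False]
        assert items[0].bh_critical == pytest.approx(0.0125)
        assert items[3].bh_critical == pytest.approx(0.05)

    def test_all_ones_nothing_significant(self):
        items = benjamini_hochberg([1.0, 1.0, 1.0], alpha=0.05)
        assert not any(i.significant for i in items)
        assert all(i.adjusted_p == 1.0 for i in items)

    def test_single_p_reduces_to_raw_threshold(self):
        (item,) = benjamini_hochberg([0.03], alpha=0.05, m=1)
        assert item.significant and item.adjusted_p == pytest.approx(0.03)

    def test_m_larger_than_list_scales_criticals(self):
        # correcting over 196 recurrent genes while supplying three p-values
        items = benjamini_hochberg([0.0001, 0.01, 0.04], alpha=0.05, m=196)
        assert items[0].bh_critical == pytest.approx(1 / 196 * 0.05)
        assert items[0].significant
        assert not items[1].significant and not items[2].significant

    def test_rejects_p_outside_unit_interval(self):
        with pytest.raises(BurdenError):
            benjamini_hochberg([0.5, 1.2])

    def test_agrees_with_statsmodels_when_m_equals_len(self):
        from statsmodels.stats.multitest import multipletests

        rng = random.Random(3)
        p = [rng.random() for _ in range(25)]
        items = benjamini_hochberg(p, alpha=0.05)
        reject, adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert [i.significant for i in items] == list(reject)
        for mine, theirs in zip(items, adj):
            assert mine.adjusted_p == pytest.approx(theirs, rel=1e-12)

    def test_significant_set_monotone_in_alpha(self):
        rng = random.Random(11)
        p = [rng.random() ** 2 for _ in range(30)]
        previous = set()
        for alpha in (0.01, 0.05, 0.10, 0.25):
            current = {
                i for i, item in enumerate(benjamini_hochberg(p, alpha=alpha))
                if item.significant
            }
            assert previous <= current
            previous = current

    def test_adjusted_p_monotone_in_raw_p(self):
        rng = random.Random(13)
        p = sorted(rng.random() for _ in range(40))
        adj = [i.adjusted_p for i in benjamini_hochberg(p, alpha=0.05)]
        assert adj == sorted(adj)


def _fv(sample, gene, pos):
    return FilteredVariant(
        make_record(sample_id=sample, gene=gene, pos=pos), IMPACT_CONSERVED_MISSENSE
    )


class TestBurdenScreen:
    def setup_method(self):
        self.case_cohort = CohortSpec(
            "disc", "discovery", {f"S{i}": f"F{i}" for i in range(1, 56)}
        )

    def recurrence_for(self, gene, carrier_count):
        records = [_fv(f"S{i + 1}", gene, 100 + i) for i in range(carrier_count)]
        return find_recurrent_genes(records, self.case_cohort)

    def test_case_only_gene_retained(self):
        rec = self.recurrence_for("G1", 3)
        screen = burden_screen(rec, 55, [], 164)
        assert screen.retained_genes == ["G1"]

    def test_proportional_gene_removed(self):
        rec = self.recurrence_for("G1", 5)
        controls = [_fv(f"C{i}", "G1", 200 + i) for i in range(15)]
        screen = burden_screen(rec, 55, controls, 164)
        assert screen.retained_genes == []
        assert "G1" in screen.removed_genes

    def test_empty_recurrence_gives_empty_result(self):
        screen = burden_screen([], 55, [], 164)
        assert screen.results == [] and screen.retained_genes == []

    def test_fingerprint_mismatch_aborts(self):
        rec = self.recurrence_for("G1", 3)
        with pytest.raises(BurdenError, match="fingerprint"):
            burden_screen(rec, 55, [], 164,
                          case_fingerprint="aaaa", control_fingerprint="bbbb")

    def test_carrier_unit_counts_samples_not_observations(self):
        variants = [_fv("S1", "G1", 1), _fv("S1", "G1", 2), _fv("S2", "G1", 3)]
        assert count_gene_burden(variants, "variants") == {"G1": 3}
        assert count_gene_burden(variants, "carriers") == {"G1": 2}
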