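"""Filter cascade: quality, frequency, impact gates and their properties."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from crcburden.filtering import (
    FilterConfig,
    FilterError,
    IMPACT_CONSERVED_MISSENSE,
    IMPACT_EXCLUDED,
    IMPACT_TRUNCATING,
    classify_impact,
    exclude_lof_tolerant,
    filter_cohort,
    passes_frequency,
    passes_quality,
)
from crcburden.model import GeneListPack, ReferencePanelCounts, VariantAnnotation, VariantCall

from conftest import make_record


def call(dp, vr, us=12, sample="S1"):
    return VariantCall(sample, "1", 100, "A", "G", dp, vr, us)


class TestQualityGate:
    def test_inclusive_boundaries_pass(self, filter_config):
        ok, failed = passes_quality(call(10, 5, 5), filter_config)
        assert ok and failed == []

    def test_fraction_just_below_28_percent_fails(self, filter_config):
        ok, failed = passes_quality(call(100, 27, 12), filter_config)
        assert not ok and failed == ["min_variant_fraction"]

    def test_indel_without_unique_starts_skips_that_rule(self, filter_config):
        ok, failed = passes_quality(call(30, 12, None), filter_config)
        assert ok

    def test_each_rule_reports_its_identifier(self, filter_config):
        _, failed = passes_quality(call(9, 2, 3), filter_config)
        assert failed == ["min_total_reads", "min_variant_reads",
                          "min_unique_starts", "min_variant_fraction"]


class TestFrequencyGate:
    def panels(self, inhouse=0, evs=0):
        return {
            "inhouse": ReferencePanelCounts("inhouse", 2037, inhouse),
            "evs": ReferencePanelCounts("evs", 6503, evs),
        }

    def test_rare_in_both_panels_passes(self, filter_config):
        # 1/13006 = 7.69e-5 <= 0.001
        assert passes_frequency(self.panels(inhouse=0, evs=1), filter_config)

    def test_common_in_one_panel_fails(self, filter_config):
        # 27/13006 = 0.00208 > 0.001
        assert not passes_frequency(self.panels(evs=27), filter_config)

    def test_all_zero_passes(self, filter_config):
        assert passes_frequency(self.panels(), filter_config)

    def test_missing_enforced_panel_is_an_error(self, filter_config):
        with pytest.raises(FilterError, match="evs"):
            passes_frequency({"inhouse": ReferencePanelCounts("inhouse", 2037, 0)},
                             filter_config)

    def test_per_panel_zero_cutoff_gives_strict_absence(self):
        config = FilterConfig(panel_max_maf={"inhouse": 0.0})
        assert not passes_frequency(self.panels(inhouse=1), config)
        assert passes_frequency(self.panels(inhouse=0, evs=1), config)


class TestImpactClassification:
    def ann(self, csq, phylop=None):
        return VariantAnnotation(gene_symbol="G", consequence=csq, phylop=phylop)

    def test_splice_site_truncating_regardless_of_low_conservation(self, filter_config):
        # mirrors a retained splice variant scored PhyloP 2.427
        assert classify_impact(self.ann("canonical_splice", 2.427), filter_config) \
            == IMPACT_TRUNCATING

    def test_conserved_missense_at_and_above_cutoff(self, filter_config):
        assert classify_impact(self.ann("missense", 4.531), filter_config) \
            == IMPACT_CONSERVED_MISSENSE
        assert classify_impact(self.ann("missense", 3.0), filter_config) \
            == IMPACT_CONSERVED_MISSENSE

    def test_missense_below_cutoff_excluded(self, filter_config):
        assert classify_impact(self.ann("missense", 2.99), filter_config) == IMPACT_EXCLUDED

    def test_synonymous_and_other_never_retained(self, filter_config):
        assert classify_impact(self.ann("synonymous", 6.0), filter_config) == IMPACT_EXCLUDED
        assert classify_impact(self.ann("other", 6.0), filter_config) == IMPACT_EXCLUDED

    def test_missense_without_phylop_excluded_with_warning(self, filter_config, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="crcburden.filtering"):
            verdict = classify_impact(self.ann("missense", None), filter_config)
        assert verdict == IMPACT_EXCLUDED
        assert any("PhyloP" in m for m in caplog.messages)

    @given(phylop=st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_truncating_verdict_independent_of_phylop(self, phylop):
        config = FilterConfig()
        for csq in ("nonsense", "frameshift", "canonical_splice"):
            assert classify_impact(self.ann(csq, phylop), config) == IMPACT_TRUNCATING


class TestLofTolerantExclusion:
    def test_removes_listed_genes_preserving_order(self):
        pack = GeneListPack("lof_tolerant", frozenset({"OR2T33"}))
        records = [make_record(gene=g, pos=i) for i, g in
                   enumerate(["A1", "OR2T33", "B1"], start=1)]
        out = exclude_lof_tolerant(records, pack)
        assert [r.gene for r in out] == ["A1", "B1"]

    def test_no_overlap_is_identity(self):
        pack = GeneListPack("lof_tolerant", frozenset({"ZZZ"}))
        records = [make_record(pos=i) for i in (1, 2)]
        assert exclude_lof_tolerant(records, pack) == records


class TestFilterCohort:
    def test_summary_partitions_retained_records(self, filter_config):
        records = (
            [make_record(sample_id="S1", pos=i, consequence="nonsense", phylop=1.0)
             for i in range(1, 6)]
            + [make_record(sample_id="S1", pos=100 + i, consequence="missense", phylop=5.0)
               for i in range(1, 30)]
        )
        result = filter_cohort(records, filter_config)
        row = result.summary.set_index("sample_id").loc["S1"]
        assert (row["n_truncating"], row["n_conserved_missense"]) == (5, 29)
        # independent recount over the output
        assert row.sum() == len(result.retained)

    def test_sample_with_no_survivors_gets_zero_row(self, filter_config):
        records = [make_record(sample_id="S9", total_reads=8, variant_reads=5)]
        result = filter_cohort(records, filter_config, sample_ids=["S9"])
        row = result.summary.set_index("sample_id").loc["S9"]
        assert (row["n_truncating"], row["n_conserved_missense"]) == (0, 0)

    def test_output_is_subset_of_input_no_duplication(self, bundle, filter_config):
        result = filter_cohort(
            bundle.discovery_records, filter_config,
            lof_tolerant=bundle.packs["lof_tolerant"],
        )
        input_ids = [(r.sample_id, r.variant_key) for r in bundle.discovery_records]
        output_ids = [(fv.sample_id, fv.variant_key) for fv in result.retained]
        assert len(output_ids) == len(set(output_ids))
        assert set(output_ids) <= set(input_ids)

    @pytest.mark.parametrize(
        "field, tighter",
        [
            ("min_total_reads", 40),
            ("min_variant_reads", 20),
            ("min_unique_starts", 15),
            ("min_variant_fraction", 0.6),
            ("max_panel_maf", 0.00001),
            ("phylop_min", 6.5),
        ],
    )
    def test_raising_any_threshold_never_grows_the_retained_set(
        self, bundle, field, tighter
    ):
        """Antitone in every scalar threshold."""
        base = FilterConfig()
        tight = FilterConfig(**{field: tighter})
        if field == "max_panel_maf":
            tight = dataclasses.replace(base, max_panel_maf=tighter)
        loose_out = {
            (fv.sample_id, fv.variant_key)
            for fv in filter_cohort(bundle.discovery_records, base).retained
        }
        tight_out = {
            (fv.sample_id, fv.variant_key)
            for fv in filter_cohort(bundle.discovery_records, tight).retained
        }
        assert tight_out <= loose_out

    def test_funnel_counts_are_non_increasing(self, bundle, filter_config):
        result = filter_cohort(bundle.discovery_records, filter_config,
                               lof_tolerant=bundle.packs["lof_tolerant"])
        stages = list(result.funnel.values())
        assert stages == sorted(stages, reverse=True)
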