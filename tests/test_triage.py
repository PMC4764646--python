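"""Known-gene annotation, four-step triage and replication selection."""

import random

import pytest

from crcburden.filtering import (
    FilterConfig,
    IMPACT_CONSERVED_MISSENSE,
    IMPACT_TRUNCATING,
)
from crcburden.model import FilteredVariant, GeneListPack
from crcburden.triage import (
    TriageError,
    annotate_known_genes,
    select_replication_variants,
    triage_candidates,
)
from crcburden.zygosity import RecurrenceRecord

from conftest import make_record


def packs_with(**overrides):
    base = {
        "crc_predisposition": {"MSH6", "MLH1", "APC"},
        "cancer_syndrome": {"BLM", "ATM"},
        "lof_tolerant": {"OR2T33"},
        "crc_driver": {"PTPN12", "TTN"},
        "mouse_transposon": {"LRP6", "PTEN"},
        "kegg_cancer_pathways": {"LRP6", "APC", "TP53"},
        "gwas": {"GREM1"},
    }
    base.update(overrides)
    return {k: GeneListPack(k, frozenset(v)) for k, v in base.items()}


def rec(gene, impacts, families=None):
    """RecurrenceRecord with one variant per impact class entry."""
    families = families or [f"F{i}" for i in range(len(impacts))]
    samples = [f"S{i}" for i in range(len(impacts))]
    variants = tuple(
        FilteredVariant(
            make_record(sample_id=s, gene=gene, pos=100 + i,
                        consequence="canonical_splice" if imp == IMPACT_TRUNCATING else "missense"),
            imp,
        )
        for i, (s, imp) in enumerate(zip(samples, impacts))
    )
    return RecurrenceRecord(
        gene_symbol=gene,
        carrier_sample_ids=tuple(samples),
        carrier_family_ids=tuple(families),
        variants=variants,
    )


T, M = IMPACT_TRUNCATING, IMPACT_CONSERVED_MISSENSE


class TestKnownGenes:
    def test_crc_and_syndrome_hits_with_follow_up_note(self):
        variants = [
            FilteredVariant(make_record(gene="MSH6", pos=1), M),
            FilteredVariant(make_record(gene="BLM", pos=2), M),
            FilteredVariant(make_record(gene="EMR3", pos=3), T),
        ]
        hits = annotate_known_genes(variants, packs_with())
        by_gene = {h.gene_symbol: h.category for h in hits}
        assert by_gene == {"MSH6": "crc_predisposition", "BLM": "cancer_syndrome"}
        assert all("follow-up" in h.interpretation_note for h in hits)

    def test_missing_pack_is_an_error(self):
        packs = packs_with()
        del packs["cancer_syndrome"]
        with pytest.raises(TriageError, match="cancer_syndrome"):
            annotate_known_genes([], packs)


class TestTriage:
    def test_all_truncating_recurrent_is_step1(self):
        out = triage_candidates([rec("EMR3", [T, T])], packs_with())
        assert out[0].retained_at_step == "step1_truncating_recurrent"

    def test_driver_gene_with_missense_is_step2(self):
        out = triage_candidates([rec("PTPN12", [M, M, M])], packs_with())
        assert out[0].retained_at_step == "step2_driver"

    def test_mouse_hit_requires_kegg_intersection(self):
        out = triage_candidates([rec("PTEN", [M, M])], packs_with())
        assert out[0].retained_at_step == "none"
        out = triage_candidates([rec("LRP6", [M, M, M])], packs_with())
        assert out[0].retained_at_step == "step3_mouse_and_kegg"

    def test_gwas_gene_is_step4(self):
        out = triage_candidates([rec("GREM1", [M, M])], packs_with())
        assert out[0].retained_at_step == "step4_gwas"

    def test_first_match_wins_and_all_matches_reported(self):
        # truncating-recurrent gene that is also on the driver list
        packs = packs_with(crc_driver={"PTPN12", "EMR3"})
        out = triage_candidates([rec("EMR3", [T, T])], packs)
        assert out[0].retained_at_step == "step1_truncating_recurrent"
        assert out[0].matched_steps == ("step1_truncating_recurrent", "step2_driver")

    def test_mixed_impacts_fail_step1(self):
        packs = packs_with()
        out = triage_candidates([rec("EMR3", [T, M])], packs)
        assert out[0].retained_at_step == "none"

    def test_truncating_pair_in_one_family_fails_step1(self):
        out = triage_candidates(
            [rec("EMR3", [T, T], families=["F1", "F1"])], packs_with()
        )
        assert out[0].retained_at_step == "none"

    def test_output_genes_subset_of_input_and_order_independent(self):
        survivors = [rec("EMR3", [T, T]), rec("PTPN12", [M, M, M]), rec("LRP6", [M, M])]
        reference = triage_candidates(survivors, packs_with())
        assert {t.gene_symbol for t in reference} == {"EMR3", "PTPN12", "LRP6"}
        rng = random.Random(5)
        for _ in range(5):
            shuffled = survivors[:]
            rng.shuffle(shuffled)
            assert triage_candidates(shuffled, packs_with()) == reference

    def test_adding_unrelated_genes_never_changes_a_verdict(self):
        survivors = [rec("PTPN12", [M, M, M])]
        before = triage_candidates(survivors, packs_with())[0]
        extended = survivors + [rec("GREM1", [M, M]), rec("ZZZ9", [M, M])]
        after = {t.gene_symbol: t for t in triage_candidates(extended, packs_with())}
        assert after["PTPN12"] == before

    def test_missing_pack_named(self):
        packs = packs_with()
        del packs["gwas"]
        with pytest.raises(TriageError, match="gwas"):
            triage_candidates([rec("EMR3", [T, T])], packs)


class TestReplicationSelection:
    def evs(self, ac):
        return {"evs": (ac, 6503)}

    def test_conserved_missense_absent_from_evs_selected(self):
        records = [make_record(gene="PTPN12", consequence="missense", phylop=4.24,
                               panels=self.evs(0))]
        out = select_replication_variants(records)
        assert len(out) == 1 and out[0].impact_class == IMPACT_CONSERVED_MISSENSE

    def test_low_conservation_missense_rejected(self):
        records = [make_record(consequence="missense", phylop=2.0, panels=self.evs(0))]
        assert select_replication_variants(records) == []

    def test_common_truncating_rejected(self):
        # EVS MAF 131/13006 = 0.01 > 0.001
        records = [make_record(consequence="nonsense", panels=self.evs(131))]
        assert select_replication_variants(records) == []

    def test_quality_gate_optional_for_amplicon_platforms(self):
        records = [make_record(consequence="missense", phylop=4.0,
                               total_reads=8, variant_reads=5, unique_starts=None,
                               panels=self.evs(0))]
        assert select_replication_variants(records, apply_quality=True) == []
        assert len(select_replication_variants(records, apply_quality=False)) == 1
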