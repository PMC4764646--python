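import pytest

from crcburden.filtering import FilterConfig
from crcburden.fixture import make_paper_fixture
from crcburden.model import (
    ReferencePanelCounts,
    VariantAnnotation,
    VariantCall,
    VariantRecord,
)


@pytest.fixture(scope="session")
def bundle():
    """The deterministic demonstration cohort (candidates + noise)."""
    return make_paper_fixture()


@pytest.fixture
def filter_config():
    return FilterConfig()


def make_record(
    sample_id="S0001",
    chrom="1",
    pos=1000,
    ref="A",
    alt="G",
    total_reads=60,
    variant_reads=30,
    unique_starts=12,
    gene="GENEX",
    consequence="missense",
    phylop=4.0,
    panels=None,
    **annotation_kwargs,
):
    """Terse builder for a fully specified record with passing defaults."""
    if panels is None:
        panels = {"inhouse": (0, 2037), "evs": (0, 6503)}
    return VariantRecord(
        call=VariantCall(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            total_reads=total_reads, variant_reads=variant_reads,
            unique_starts=unique_starts,
        ),
        annotation=VariantAnnotation(
            gene_symbol=gene, consequence=consequence, phylop=phylop,
            **annotation_kwargs,
        ),
        panels={
            panel: ReferencePanelCounts(panel, n, ac)
            for panel, (ac, n) in panels.items()
        },
    )
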