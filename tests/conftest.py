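import pytest

from doublehit import (
    Assertion,
    Consequence,
    GeneClass,
    GenePanelEntry,
    GermlineVariantRecord,
    PolyPhen,
    Sift,
    SimConfig,
    SomaticMutationRecord,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_panel():
    return [
        GenePanelEntry("TP53L", GeneClass.TSG, "chr17", 100, 200),
        GenePanelEntry("BRCA2L", GeneClass.TSG, "chr13", 1_000, 90_000),
        GenePanelEntry("KRASL", GeneClass.ONCOGENE, "chr12", 500, 900),
        GenePanelEntry("MISC1", GeneClass.NON_CLASSIFIED, "chr1", 10, 50),
    ]


@pytest.fixture(scope="session")
def panel_by_symbol(small_panel):
    return {e.gene_symbol: e for e in small_panel}


def make_germline(sample="S1", gene="TP53L", assertion=Assertion.PATHOGENIC,
                  pop_afs=None, tumor_vaf=None, pos=150,
                  consequence=Consequence.MISSENSE):
    return GermlineVariantRecord(
        sample_id=sample, gene_symbol=gene, chrom="chr17", pos=pos,
        ref="C", alt="T", consequence=consequence, assertion=assertion,
        pop_afs={"gnomad": 0.001} if pop_afs is None else pop_afs,
        tumor_vaf=tumor_vaf)


def make_somatic(sample="S1", gene="TP53L", consequence=Consequence.FRAMESHIFT,
                 sift=Sift.ABSENT, polyphen=PolyPhen.ABSENT, cadd=None,
                 pos=160, protein_pos=50, tumor_vaf=0.3):
    return SomaticMutationRecord(
        sample_id=sample, gene_symbol=gene, chrom="chr17", pos=pos,
        ref="G", alt="A", consequence=consequence, protein_pos=protein_pos,
        sift=sift, polyphen=polyphen, cadd=cadd, tumor_vaf=tumor_vaf)


@pytest.fixture(scope="session")
def sim_cohort():
    """Mid-size noise-free cohort reused by read-only tests."""
    return simulate_cohort(SimConfig(seed=5, n_cases=250))
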