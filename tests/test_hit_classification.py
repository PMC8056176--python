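"""Hit-classification rules: AF filter, predictor vote, allele-loss map."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doublehit import (
    Assertion,
    Consequence,
    CopyNumberSegment,
    GenePanelEntry,
    GeneClass,
    HitType,
    PolyPhen,
    ScnvCategory,
    Sift,
    classify_allele_loss,
    classify_germline_hit,
    classify_somatic_hit,
    collect_hits,
    gene_allele_loss,
    passes_af_filter,
    predictor_vote,
    proximity_match,
)
from conftest import make_germline, make_somatic


# ---------------------------------------------------------------------------
# Population allele-frequency filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("afs,expected", [
    ({"gnomad": 0.004}, True),
    ({"gnomad": 0.005}, True),                      # inclusive threshold
    ({"gnomad": 0.003, "other": 0.006}, False),     # max over populations
    ({}, True),                                     # unobserved = rare
    ({"gnomad": 0.0}, True),
])
def test_af_filter(afs, expected):
    assert passes_af_filter(afs) is expected


def test_af_filter_rejects_invalid_frequency():
    with pytest.raises(ValueError):
        passes_af_filter({"gnomad": 1.5})


@settings(deadline=None, max_examples=100)
@given(afs=st.dictionaries(st.sampled_from(["gnomad", "chinamap", "eas"]),
                           st.floats(0, 1), max_size=3),
       t1=st.floats(0, 1), t2=st.floats(0, 1))
def test_af_filter_monotone_in_threshold(afs, t1, t2):
    lo, hi = sorted((t1, t2))
    if passes_af_filter(afs, lo):
        assert passes_af_filter(afs, hi)
    assert passes_af_filter(afs, 1.0)


# ---------------------------------------------------------------------------
# Germline hit rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs,is_hit", [
    (dict(assertion=Assertion.PATHOGENIC, pop_afs={"gnomad": 0.001}), True),
    (dict(assertion=Assertion.LIKELY_PATHOGENIC, pop_afs={}), True),
    (dict(assertion=Assertion.UNCERTAIN, pop_afs={"gnomad": 0.001}), False),
    (dict(assertion=Assertion.PATHOGENIC, pop_afs={"gnomad": 0.02}), False),
    (dict(assertion=Assertion.BENIGN, pop_afs={}), False),
])
def test_germline_hit_rule(panel_by_symbol, kwargs, is_hit):
    hit = classify_germline_hit(make_germline(**kwargs), panel_by_symbol)
    assert (hit is not None) is is_hit
    if hit:
        assert hit.hit_type is HitType.GERMLINE_PATHOGENIC


def test_germline_gene_outside_panel(panel_by_symbol):
    v = make_germline(gene="NOT_A_PANEL_GENE")
    assert classify_germline_hit(v, panel_by_symbol) is None


def test_benign_cohort_yields_zero_hits(small_panel):
    variants = [make_germline(sample=f"S{i}", assertion=a)
                for i in range(10)
                for a in (Assertion.BENIGN, Assertion.LIKELY_BENIGN,
                          Assertion.UNCERTAIN, Assertion.NONE)]
    hits = collect_hits(variants, [], [], small_panel)
    assert hits == []


# ---------------------------------------------------------------------------
# Predictor vote — exhaustive over the small domain
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sift", list(Sift))
@pytest.mark.parametrize("polyphen", list(PolyPhen))
@pytest.mark.parametrize("cadd", [None, 0.0, 10.0, 15.0, 15.0001, 16.0, 40.0])
def test_predictor_vote_exhaustive(sift, polyphen, cadd):
    expected = ((sift is Sift.D)
                + (polyphen in (PolyPhen.D, PolyPhen.P))
                + (cadd is not None and cadd > 15.0))
    votes, deleterious = predictor_vote(sift, polyphen, cadd)
    assert votes == expected
    assert deleterious is (expected >= 2)


@pytest.mark.parametrize("args,expected", [
    ((Sift.D, PolyPhen.P, 14.0), (2, True)),
    ((Sift.T, PolyPhen.B, 16.0), (1, False)),
    ((Sift.D, PolyPhen.ABSENT, 15.0), (1, False)),   # 15 is not > 15
    ((Sift.D, PolyPhen.D, 20.0), (3, True)),
])
def test_predictor_vote_examples(args, expected):
    assert tuple(predictor_vote(*args)) == expected


@settings(deadline=None, max_examples=100)
@given(sift=st.sampled_from(list(Sift)),
       polyphen=st.sampled_from(list(PolyPhen)),
       cadd=st.one_of(st.none(), st.floats(0, 60)))
def test_predictor_vote_monotone(sift, polyphen, cadd):
    """Upgrading any single tool to damaging never loses the call."""
    base = predictor_vote(sift, polyphen, cadd)
    for upgraded in (predictor_vote(Sift.D, polyphen, cadd),
                     predictor_vote(sift, PolyPhen.D, cadd),
                     predictor_vote(sift, polyphen, 40.0)):
        assert upgraded.votes >= base.votes
        assert upgraded.deleterious >= base.deleterious


# ---------------------------------------------------------------------------
# Somatic hit rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs,is_hit", [
    (dict(consequence=Consequence.FRAMESHIFT), True),
    (dict(consequence=Consequence.NONSENSE), True),
    (dict(consequence=Consequence.SPLICE_SITE), True),
    (dict(consequence=Consequence.MISSENSE, sift=Sift.D,
          polyphen=PolyPhen.P, cadd=10.0), True),
    (dict(consequence=Consequence.MISSENSE, sift=Sift.D), False),
    (dict(consequence=Consequence.SYNONYMOUS, sift=Sift.D,
          polyphen=PolyPhen.D, cadd=30.0), False),
    (dict(consequence=Consequence.OTHER), False),
])
def test_somatic_hit_rule(panel_by_symbol, kwargs, is_hit):
    hit = classify_somatic_hit(make_somatic(**kwargs), panel_by_symbol)
    assert (hit is not None) is is_hit


@pytest.mark.parametrize("rule,cadd,is_hit", [
    ("cadd_only", 16.0, True),
    ("cadd_only", 15.0, False),
    ("cadd_only", None, False),
    ("two_votes", 16.0, False),     # one vote cannot reach two
])
def test_inframe_indel_rules(panel_by_symbol, rule, cadd, is_hit):
    m = make_somatic(consequence=Consequence.INFRAME_INDEL, cadd=cadd)
    hit = classify_somatic_hit(m, panel_by_symbol, inframe_rule=rule)
    assert (hit is not None) is is_hit


def test_somatic_gene_outside_panel(panel_by_symbol):
    m = make_somatic(gene="NOT_A_PANEL_GENE")
    assert classify_somatic_hit(m, panel_by_symbol) is None


# ---------------------------------------------------------------------------
# Allele-loss category map — exhaustive over the valid small domain
# ---------------------------------------------------------------------------

def _expected_category(tcn, lcn):
    if tcn == 0:
        return ScnvCategory.HOMOZYGOUS_DELETION
    if tcn == 1:
        return ScnvCategory.HEMIZYGOUS_DELETION
    if lcn == 0:
        return (ScnvCategory.COPY_NEUTRAL_LOH if tcn == 2
                else ScnvCategory.DUPLICATION_LOH)
    return None


def test_allele_loss_map_exhaustive():
    """The (tcn, lcn) -> category map, checked over every valid state
    with total copy number up to 8 (plus unknown minor copy number)."""
    checked = 0
    for tcn in range(9):
        for lcn in [None] + list(range(tcn // 2 + 1)):
            assert classify_allele_loss(tcn, lcn) == _expected_category(tcn, lcn)
            checked += 1
    assert checked > 20


def test_allele_loss_invalid_state_rejected():
    with pytest.raises(ValueError):
        classify_allele_loss(3, 2)      # minor exceeds half of total
    with pytest.raises(ValueError):
        classify_allele_loss(-1, None)


# ---------------------------------------------------------------------------
# Per-gene allele-loss lookup
# ---------------------------------------------------------------------------

def test_gene_allele_loss_overlap_and_priority():
    gene = GenePanelEntry("G", GeneClass.TSG, "chr17", 100, 200)
    hemi = CopyNumberSegment("S1", "chr17", 150, 300, 1, 0)
    cnloh = CopyNumberSegment("S1", "chr17", 90, 160, 2, 0)
    other_chrom = CopyNumberSegment("S1", "chr2", 1, 10**6, 0, 0)
    retained = CopyNumberSegment("S1", "chr17", 100, 200, 2, 1)

    assert gene_allele_loss([hemi], gene)[0] is ScnvCategory.HEMIZYGOUS_DELETION
    assert gene_allele_loss([other_chrom], gene) is None
    assert gene_allele_loss([retained], gene) is None
    # deeper loss wins regardless of input order
    assert gene_allele_loss([cnloh, hemi], gene)[0] is \
        ScnvCategory.HEMIZYGOUS_DELETION
    assert gene_allele_loss([hemi, cnloh], gene)[0] is \
        ScnvCategory.HEMIZYGOUS_DELETION
    # single-base overlap at the interval edge counts
    edge = CopyNumberSegment("S1", "chr17", 200, 500, 0, 0)
    assert gene_allele_loss([edge], gene)[0] is ScnvCategory.HOMOZYGOUS_DELETION
    # adjacent but non-overlapping does not
    outside = CopyNumberSegment("S1", "chr17", 201, 500, 0, 0)
    assert gene_allele_loss([outside], gene) is None


# ---------------------------------------------------------------------------
# Proximity match
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pos,catalog,expected", [
    (100, {103}, True),
    (100, {106}, False),
    (100, {100}, True),
    (100, {105}, True),       # boundary: exactly five away
    (100, set(), False),
    (3, {1, 200}, True),
])
def test_proximity_match(pos, catalog, expected):
    assert proximity_match(pos, catalog) is expected


def test_proximity_match_rejects_bad_positions():
    with pytest.raises(ValueError):
        proximity_match(0, {5})
    with pytest.raises(ValueError):
        proximity_match(10, {0})
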