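"""Classification of germline, somatic, and copy-number "hits".

A *hit* is one inactivating lesion in a susceptibility gene in one sample:

* a germline variant with a pathogenic / likely-pathogenic assertion that is
  rare (population allele frequency <= 0.5%) and falls in a panel gene;
* a somatic mutation that truncates (frameshift, nonsense, splice-site) or is
  a missense / in-frame change called deleterious by a 2-of-3 vote over SIFT,
  PolyPhen-2 HDIV, and CADD;
* a somatic copy-number state implying loss of one parental allele
  (homozygous deletion, hemizygous deletion, copy-neutral LOH, duplication
  LOH) overlapping a panel gene.

Two or more hits in the same tumor-suppressor gene form a candidate
double-hit event (see :mod:`doublehit.doublehit_caller`).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

from .cohort_model import (
    Consequence,
    CopyNumberSegment,
    FormatError,
    GenePanelEntry,
    GermlineVariantRecord,
    PathLike,
    PolyPhen,
    ScnvCategory,
    Sift,
    SomaticMutationRecord,
    _iter_rows,
    _open,
    Assertion,
)

logger = logging.getLogger("doublehit")

#: Population allele-frequency ceiling for a germline variant to count as rare.
AF_THRESHOLD = 0.005
#: CADD score above which (strictly) the CADD predictor votes "damaging".
CADD_CUTOFF = 15.0
#: Minimum number of damaging predictor votes for a deleterious call.
MIN_VOTES = 2


class HitType(str, enum.Enum):
    GERMLINE_PATHOGENIC = "germline_pathogenic"
    SOMATIC_MUTATION = "somatic_mutation"
    ALLELE_LOSS_SCNV = "allele_loss_scnv"


Evidence = Union[GermlineVariantRecord, SomaticMutationRecord,
                 CopyNumberSegment, str]


@dataclass(frozen=True)
class Hit:
    sample_id: str
    gene_symbol: str
    hit_type: HitType
    scnv_category: Optional[ScnvCategory] = None
    evidence: Optional[Evidence] = None
    #: tumor VAF of the underlying variant (carried so that hits written to
    #: disk still support downstream VAF validation); None for SCNV hits
    tumor_vaf: Optional[float] = None

    def __post_init__(self) -> None:
        has_cat = self.scnv_category is not None
        if has_cat != (self.hit_type is HitType.ALLELE_LOSS_SCNV):
            raise ValueError(
                "scnv_category must be present iff hit_type is allele_loss_scnv")
        if self.tumor_vaf is not None and not (0.0 <= self.tumor_vaf <= 1.0):
            raise ValueError(f"tumor_vaf {self.tumor_vaf} outside [0, 1]")

    @property
    def evidence_pointer(self) -> str:
        ev = self.evidence
        if ev is None:
            return ""
        if isinstance(ev, str):
            return ev
        if isinstance(ev, CopyNumberSegment):
            lcn = "NA" if ev.lcn is None else ev.lcn
            return f"{ev.chrom}:{ev.start}-{ev.end}:tcn={ev.tcn},lcn={lcn}"
        return ev.variant_id


# ---------------------------------------------------------------------------
# Germline hits
# ---------------------------------------------------------------------------

PATHOGENIC_ASSERTIONS = frozenset({Assertion.PATHOGENIC,
                                   Assertion.LIKELY_PATHOGENIC})


def passes_af_filter(pop_afs: Mapping[str, float],
                     threshold: float = AF_THRESHOLD) -> bool:
    """True iff the variant is rare in every supplied population.

    The rule is inclusive (a frequency exactly at the threshold passes) and
    takes the maximum over present populations.  A variant absent from every
    frequency database passes: unobserved variants cannot exceed the
    threshold.
    """
    for pop, af in pop_afs.items():
        if not (0.0 <= af <= 1.0):
            raise ValueError(f"allele frequency {af} for {pop} outside [0, 1]")
    if not pop_afs:
        return True
    return max(pop_afs.values()) <= threshold


def classify_germline_hit(v: GermlineVariantRecord,
                          panel: Mapping[str, GenePanelEntry],
                          af_threshold: float = AF_THRESHOLD) -> Optional[Hit]:
    """Call a germline pathogenic hit, or ``None``.

    Requires a pathogenic / likely-pathogenic assertion, rarity under the
    allele-frequency filter, and membership of the gene panel.  Both het and
    hom genotypes count once.  A gene missing from the panel is logged, not
    an error.
    """
    if v.gene_symbol not in panel:
        logger.debug("germline variant %s in %s: gene not in panel",
                     v.variant_id, v.gene_symbol)
        return None
    if v.assertion not in PATHOGENIC_ASSERTIONS:
        return None
    if not passes_af_filter(v.pop_afs, af_threshold):
        return None
    return Hit(v.sample_id, v.gene_symbol, HitType.GERMLINE_PATHOGENIC,
               evidence=v, tumor_vaf=v.tumor_vaf)


# ---------------------------------------------------------------------------
# Somatic mutation hits
# ---------------------------------------------------------------------------

class PredictorVote(NamedTuple):
    votes: int
    deleterious: bool


def predictor_vote(sift: Sift, polyphen: PolyPhen,
                   cadd: Optional[float]) -> PredictorVote:
    """2-of-3 damaging vote over SIFT, PolyPhen-2 HDIV, and CADD.

    SIFT votes on ``D``; PolyPhen on ``D`` or ``P``; CADD on a score
    strictly above 15.  An absent annotation never votes.
    """
    votes = 0
    if sift is Sift.D:
        votes += 1
    if polyphen in (PolyPhen.D, PolyPhen.P):
        votes += 1
    if cadd is not None and cadd > CADD_CUTOFF:
        votes += 1
    return PredictorVote(votes, votes >= MIN_VOTES)


#: consequence classes that are hits without predictor support
TRUNCATING = frozenset({Consequence.FRAMESHIFT, Consequence.NONSENSE,
                        Consequence.SPLICE_SITE})


def classify_somatic_hit(m: SomaticMutationRecord,
                         panel: Mapping[str, GenePanelEntry],
                         inframe_rule: str = "cadd_only") -> Optional[Hit]:
    """Call a somatic mutation hit, or ``None``.

    Truncating classes (frameshift, nonsense, splice-site) qualify
    automatically; missense qualifies when the 2-of-3 predictor vote is
    deleterious.  In-frame indels have no SIFT/PolyPhen output, so under the
    default ``inframe_rule="cadd_only"`` they qualify on CADD > 15 alone;
    ``inframe_rule="two_votes"`` subjects them to the full vote (excluding
    essentially all of them).  Synonymous and other classes never qualify.
    """
    if inframe_rule not in ("cadd_only", "two_votes"):
        raise ValueError(f"unknown inframe_rule {inframe_rule!r}")
    if m.gene_symbol not in panel:
        return None
    qualifies = False
    if m.consequence in TRUNCATING:
        qualifies = True
    elif m.consequence is Consequence.MISSENSE:
        qualifies = predictor_vote(m.sift, m.polyphen, m.cadd).deleterious
    elif m.consequence is Consequence.INFRAME_INDEL:
        if inframe_rule == "cadd_only":
            qualifies = m.cadd is not None and m.cadd > CADD_CUTOFF
        else:
            qualifies = predictor_vote(m.sift, m.polyphen, m.cadd).deleterious
    if not qualifies:
        return None
    return Hit(m.sample_id, m.gene_symbol, HitType.SOMATIC_MUTATION,
               evidence=m, tumor_vaf=m.tumor_vaf)


# ---------------------------------------------------------------------------
# Allele-loss SCNV hits
# ---------------------------------------------------------------------------

def classify_allele_loss(tcn: int, lcn: Optional[int]) -> Optional[ScnvCategory]:
    """Map an allele-specific copy-number state to an allele-loss category.

    tcn=0 -> homozygous deletion; tcn=1 -> hemizygous deletion; tcn=2 with
    lcn=0 -> copy-neutral LOH; tcn>=3 with lcn=0 -> duplication LOH.  A
    retained minor allele (lcn >= 1), or an unknown minor copy number at
    tcn >= 2, is not allele loss.
    """
    # re-validate: this is also the entry point for raw (tcn, lcn) pairs
    CopyNumberSegment("_", "_", 1, 1, tcn=tcn, lcn=lcn)
    if tcn == 0:
        return ScnvCategory.HOMOZYGOUS_DELETION
    if tcn == 1:
        return ScnvCategory.HEMIZYGOUS_DELETION
    if lcn == 0:
        return (ScnvCategory.COPY_NEUTRAL_LOH if tcn == 2
                else ScnvCategory.DUPLICATION_LOH)
    return None


#: tie-break priority when several allele-loss segments overlap one gene
_CATEGORY_PRIORITY = {
    ScnvCategory.HOMOZYGOUS_DELETION: 0,
    ScnvCategory.HEMIZYGOUS_DELETION: 1,
    ScnvCategory.COPY_NEUTRAL_LOH: 2,
    ScnvCategory.DUPLICATION_LOH: 3,
}


def gene_allele_loss(segments: Sequence[CopyNumberSegment],
                     gene: GenePanelEntry,
                     ) -> Optional[tuple[ScnvCategory, CopyNumberSegment]]:
    """Allele-loss state of one gene in one sample.

    Returns the category (with its supporting segment) of an allele-loss
    segment overlapping the gene interval by at least one base; when several
    overlap, deeper losses win (homozygous > hemizygous > copy-neutral LOH >
    duplication LOH).  ``None`` when no overlapping segment implies allele
    loss.
    """
    best: Optional[tuple[ScnvCategory, CopyNumberSegment]] = None
    for seg in segments:
        if not seg.overlaps(gene.chrom, gene.start, gene.end):
            continue
        cat = classify_allele_loss(seg.tcn, seg.lcn)
        if cat is None:
            continue
        if best is None or _CATEGORY_PRIORITY[cat] < _CATEGORY_PRIORITY[best[0]]:
            best = (cat, seg)
    return best


# ---------------------------------------------------------------------------
# COSMIC-style proximity match
# ---------------------------------------------------------------------------

def proximity_match(germline_protein_pos: int,
                    somatic_catalog_positions: Iterable[int],
                    window: int = 5) -> bool:
    """True iff a catalogued somatic mutation sits at the same or a nearby
    (within ``window``) amino-acid position as the germline variant."""
    if germline_protein_pos < 1:
        raise ValueError("protein positions are 1-based")
    for p in somatic_catalog_positions:
        if p < 1:
            raise ValueError("protein positions are 1-based")
        if abs(p - germline_protein_pos) <= window:
            return True
    return False


# ---------------------------------------------------------------------------
# Cohort-level hit collection and hits-table IO
# ---------------------------------------------------------------------------

def collect_hits(germline: Iterable[GermlineVariantRecord],
                 somatic: Iterable[SomaticMutationRecord],
                 segments: Iterable[CopyNumberSegment],
                 panel: Sequence[GenePanelEntry],
                 af_threshold: float = AF_THRESHOLD,
                 inframe_rule: str = "cadd_only") -> list[Hit]:
    """Classify every record of a cohort into hits.

    Allele-loss hits are emitted once per (sample, gene): the deepest loss
    overlapping the gene interval wins.  Order is deterministic (germline,
    somatic, then allele loss; input order within each).
    """
    panel_by_symbol = {e.gene_symbol: e for e in panel}
    hits: list[Hit] = []
    for v in germline:
        hit = classify_germline_hit(v, panel_by_symbol, af_threshold)
        if hit is not None:
            hits.append(hit)
    for m in somatic:
        hit = classify_somatic_hit(m, panel_by_symbol, inframe_rule)
        if hit is not None:
            hits.append(hit)
    by_sample: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    for sample_id in sorted(by_sample):
        sample_segments = by_sample[sample_id]
        for entry in panel:
            found = gene_allele_loss(sample_segments, entry)
            if found is not None:
                cat, seg = found
                hits.append(Hit(sample_id, entry.gene_symbol,
                                HitType.ALLELE_LOSS_SCNV, scnv_category=cat,
                                evidence=seg))
    return hits


HITS_COLUMNS = ("sample_id", "gene_symbol", "hit_type", "scnv_category",
                "evidence", "tumor_vaf")


def write_hits(hits: Iterable[Hit], path: PathLike) -> None:
    with _open(path, "w") as fh:
        fh.write("\t".join(HITS_COLUMNS) + "\n")
        for h in hits:
            cat = "" if h.scnv_category is None else h.scnv_category.value
            vaf = "" if h.tumor_vaf is None else repr(h.tumor_vaf)
            fh.write(f"{h.sample_id}\t{h.gene_symbol}\t{h.hit_type.value}\t"
                     f"{cat}\t{h.evidence_pointer}\t{vaf}\n")


def read_hits(path: PathLike) -> list[Hit]:
    """Read a hits TSV back; evidence comes back as an opaque pointer string."""
    hits: list[Hit] = []
    for lineno, row in _iter_rows(path, HITS_COLUMNS):
        try:
            hit_type = HitType(row["hit_type"])
            cat = (ScnvCategory(row["scnv_category"])
                   if row["scnv_category"] else None)
            vaf = float(row["tumor_vaf"]) if row["tumor_vaf"] else None
            hits.append(Hit(row["sample_id"], row["gene_symbol"], hit_type,
                            scnv_category=cat,
                            evidence=row["evidence"] or None,
                            tumor_vaf=vaf))
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno) from None
    return hits
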