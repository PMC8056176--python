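"""Double-hit event calling on per-(sample, gene) hit groups.

Under the two-hit hypothesis a tumor-suppressor gene is inactivated when both
alleles are lost.  This module aggregates classified hits per (sample, gene),
emits at most one event per pair for tumor-suppressor genes with two or more
hits spanning an eligible combination, and validates events whose second hit
is an allele-loss copy-number change: if the wild-type allele was really
lost, the germline variant's tumor VAF should be at least 0.5, so events with
tumor VAF strictly below 0.5 are removed.

Eligible combinations and the subtype priority when several coexist:

1. germline pathogenic + somatic mutation  -> germline_plus_somatic_mutation
2. germline pathogenic + allele-loss SCNV  -> germline_plus_allele_loss
3. somatic mutation + allele-loss SCNV     -> somatic_plus_allele_loss
4. two somatic mutations                   -> double_somatic_mutation

Two germline variants alone (candidate compound heterozygotes) form no event
but are reported separately.  Two overlapping allele-loss states alone form
no event either: a copy-number hit only counts alongside a mutation.
"""

from __future__ import annotations

import enum
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .cohort_model import ClinicalRecord, FormatError, PathLike, _iter_rows, _open
from .hit_classification import Hit, HitType

logger = logging.getLogger("doublehit")


class EventClass(str, enum.Enum):
    GERMLINE_SOMATIC = "germline_somatic"
    SOMATIC_SOMATIC = "somatic_somatic"


class EventSubtype(str, enum.Enum):
    GERMLINE_PLUS_SOMATIC_MUTATION = "germline_plus_somatic_mutation"
    GERMLINE_PLUS_ALLELE_LOSS = "germline_plus_allele_loss"
    SOMATIC_PLUS_ALLELE_LOSS = "somatic_plus_allele_loss"
    DOUBLE_SOMATIC_MUTATION = "double_somatic_mutation"


_SUBTYPE_CLASS = {
    EventSubtype.GERMLINE_PLUS_SOMATIC_MUTATION: EventClass.GERMLINE_SOMATIC,
    EventSubtype.GERMLINE_PLUS_ALLELE_LOSS: EventClass.GERMLINE_SOMATIC,
    EventSubtype.SOMATIC_PLUS_ALLELE_LOSS: EventClass.SOMATIC_SOMATIC,
    EventSubtype.DOUBLE_SOMATIC_MUTATION: EventClass.SOMATIC_SOMATIC,
}


@dataclass(frozen=True)
class DoubleHitEvent:
    sample_id: str
    gene_symbol: str
    event_class: EventClass
    subtype: EventSubtype
    #: True once the tumor-VAF check has been applied and passed; meaningful
    #: only for germline_plus_allele_loss events
    vaf_validated: bool
    hits: tuple[Hit, ...]
    #: double somatic mutations are assumed in trans (no phasing attempted)
    trans_assumed: bool = False
    #: True when several eligible combinations coexisted and the priority
    #: rule picked this subtype
    ambiguous_subtype: bool = False

    def __post_init__(self) -> None:
        if _SUBTYPE_CLASS[self.subtype] is not self.event_class:
            raise ValueError(f"subtype {self.subtype.value} inconsistent with "
                             f"class {self.event_class.value}")
        if len(self.hits) < 2:
            raise ValueError("a double-hit event needs >= 2 contributing hits")

    @property
    def germline_tumor_vaf(self) -> Optional[float]:
        for h in self.hits:
            if h.hit_type is HitType.GERMLINE_PATHOGENIC:
                return h.tumor_vaf
        return None


# ---------------------------------------------------------------------------
# Event calling
# ---------------------------------------------------------------------------

def call_event(hits: Sequence[Hit], gene_class: str) -> Optional[DoubleHitEvent]:
    """Call at most one double-hit event from the hits of one (sample, gene).

    Only tumor-suppressor genes are eligible.  The first eligible
    combination in priority order (germline+somatic mutation, germline+allele
    loss, somatic mutation+allele loss, double somatic mutation) is emitted;
    if more than one combination exists the event is flagged ambiguous.
    """
    if not hits:
        return None
    samples = {h.sample_id for h in hits}
    genes = {h.gene_symbol for h in hits}
    if len(samples) > 1 or len(genes) > 1:
        raise ValueError(f"hits span multiple samples/genes: "
                         f"{sorted(samples)} / {sorted(genes)}")
    gene_class = getattr(gene_class, "value", gene_class)
    if gene_class != "TSG":
        return None

    germ = [h for h in hits if h.hit_type is HitType.GERMLINE_PATHOGENIC]
    som = [h for h in hits if h.hit_type is HitType.SOMATIC_MUTATION]
    loss = [h for h in hits if h.hit_type is HitType.ALLELE_LOSS_SCNV]

    candidates: list[tuple[EventSubtype, tuple[Hit, ...]]] = []
    if germ and som:
        candidates.append((EventSubtype.GERMLINE_PLUS_SOMATIC_MUTATION,
                           (germ[0], som[0])))
    if germ and loss:
        candidates.append((EventSubtype.GERMLINE_PLUS_ALLELE_LOSS,
                           (germ[0], loss[0])))
    if som and loss:
        candidates.append((EventSubtype.SOMATIC_PLUS_ALLELE_LOSS,
                           (som[0], loss[0])))
    if len(som) >= 2:
        candidates.append((EventSubtype.DOUBLE_SOMATIC_MUTATION,
                           (som[0], som[1])))
    if not candidates:
        return None

    subtype, contributing = candidates[0]
    return DoubleHitEvent(
        sample_id=hits[0].sample_id,
        gene_symbol=hits[0].gene_symbol,
        event_class=_SUBTYPE_CLASS[subtype],
        subtype=subtype,
        vaf_validated=False,
        hits=contributing,
        trans_assumed=subtype is EventSubtype.DOUBLE_SOMATIC_MUTATION,
        ambiguous_subtype=len(candidates) > 1,
    )


def call_events(hits: Iterable[Hit],
                gene_classes: Mapping[str, str],
                ) -> tuple[list[DoubleHitEvent], list[tuple[str, str]]]:
    """Group hits per (sample, gene) and call events across a cohort.

    Returns the events plus a side report of candidate compound
    heterozygotes: (sample, gene) pairs whose only multiplicity is two or
    more germline hits, which the event taxonomy deliberately excludes.
    """
    groups: dict[tuple[str, str], list[Hit]] = {}
    for h in hits:
        groups.setdefault((h.sample_id, h.gene_symbol), []).append(h)
    events: list[DoubleHitEvent] = []
    compound_het: list[tuple[str, str]] = []
    for (sample_id, gene), group in sorted(groups.items()):
        gene_class = gene_classes.get(gene)
        if gene_class is None:
            logger.warning("gene %s missing from panel classes; skipped", gene)
            continue
        event = call_event(group, gene_class)
        if event is not None:
            events.append(event)
        elif (getattr(gene_class, "value", gene_class) == "TSG"
              and sum(h.hit_type is HitType.GERMLINE_PATHOGENIC
                      for h in group) >= 2):
            compound_het.append((sample_id, gene))
    return events, compound_het


# ---------------------------------------------------------------------------
# VAF validation
# ---------------------------------------------------------------------------

VAF_CUTOFF = 0.5


def vaf_validate(event: DoubleHitEvent, tumor_vaf: Optional[float],
                 missing: str = "keep") -> bool:
    """Keep (True) or remove (False) a germline+allele-loss event by tumor VAF.

    If the wild-type allele was lost, the germline variant should be enriched
    in the tumor: events with tumor VAF strictly below 0.5 are removed; a VAF
    of exactly 0.5 keeps.  ``missing`` controls absent VAFs: ``"keep"``
    (default, with a logged warning) or ``"remove"``.
    """
    if event.subtype is not EventSubtype.GERMLINE_PLUS_ALLELE_LOSS:
        raise ValueError("VAF validation applies only to "
                         "germline_plus_allele_loss events")
    if missing not in ("keep", "remove"):
        raise ValueError(f"unknown missing-VAF policy {missing!r}")
    if tumor_vaf is None:
        if missing == "keep":
            logger.warning("event %s/%s: germline tumor VAF missing; kept",
                           event.sample_id, event.gene_symbol)
            return True
        return False
    if not (0.0 <= tumor_vaf <= 1.0):
        raise ValueError(f"tumor_vaf {tumor_vaf} outside [0, 1]")
    return tumor_vaf >= VAF_CUTOFF


def apply_vaf_validation(events: Iterable[DoubleHitEvent],
                         missing: str = "keep") -> list[DoubleHitEvent]:
    """Filter a cohort's events through the tumor-VAF check.

    Only germline_plus_allele_loss events are subject to the check; survivors
    are returned with ``vaf_validated=True``; other subtypes pass unchanged.
    """
    kept: list[DoubleHitEvent] = []
    for ev in events:
        if ev.subtype is not EventSubtype.GERMLINE_PLUS_ALLELE_LOSS:
            kept.append(ev)
            continue
        if vaf_validate(ev, ev.germline_tumor_vaf, missing=missing):
            kept.append(DoubleHitEvent(
                ev.sample_id, ev.gene_symbol, ev.event_class, ev.subtype,
                vaf_validated=True, hits=ev.hits,
                trans_assumed=ev.trans_assumed,
                ambiguous_subtype=ev.ambiguous_subtype))
    return kept


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class EventSummary:
    class_counts: dict[str, int] = field(default_factory=dict)
    subtype_counts: dict[str, int] = field(default_factory=dict)
    per_gene_counts: dict[str, int] = field(default_factory=dict)
    n_events: int = 0
    n_patients: int = 0
    #: ages of patients carrying >= 1 germline/somatic event
    ages_germline_somatic: list[float] = field(default_factory=list)
    #: ages of patients carrying somatic/somatic events only
    ages_somatic_somatic: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def summarize_events(events: Sequence[DoubleHitEvent],
                     clinical: Iterable[ClinicalRecord]) -> EventSummary:
    """Count events by class, subtype, and gene, and build the two age vectors.

    A patient with events in several genes contributes one event per gene but
    once to the patient tally.  For the age comparison a patient carrying any
    germline/somatic event goes to that group (they carry a pathogenic
    germline variant); patients with somatic/somatic events only form the
    other group.  Patients without a recorded age are counted but contribute
    no age.
    """
    summary = EventSummary(
        class_counts={c.value: 0 for c in EventClass},
        subtype_counts={s.value: 0 for s in EventSubtype},
    )
    ages = {c.sample_id: c.age_at_diagnosis for c in clinical}
    by_patient: dict[str, set[EventClass]] = {}
    gene_counter: Counter[str] = Counter()
    for ev in events:
        summary.class_counts[ev.event_class.value] += 1
        summary.subtype_counts[ev.subtype.value] += 1
        gene_counter[ev.gene_symbol] += 1
        by_patient.setdefault(ev.sample_id, set()).add(ev.event_class)
    summary.per_gene_counts = dict(sorted(gene_counter.items()))
    summary.n_events = len(events)
    summary.n_patients = len(by_patient)
    for sample_id in sorted(by_patient):
        age = ages.get(sample_id)
        if age is None:
            continue
        if EventClass.GERMLINE_SOMATIC in by_patient[sample_id]:
            summary.ages_germline_somatic.append(age)
        else:
            summary.ages_somatic_somatic.append(age)
    return summary


# ---------------------------------------------------------------------------
# Events-table IO
# ---------------------------------------------------------------------------

EVENTS_COLUMNS = ("sample_id", "gene_symbol", "event_class", "subtype",
                  "vaf_validated", "trans_assumed", "ambiguous_subtype",
                  "germline_tumor_vaf", "evidence")


def write_events(events: Iterable[DoubleHitEvent], path: PathLike) -> None:
    with _open(path, "w") as fh:
        fh.write("\t".join(EVENTS_COLUMNS) + "\n")
        for ev in events:
            vaf = ev.germline_tumor_vaf
            fh.write("\t".join([
                ev.sample_id, ev.gene_symbol, ev.event_class.value,
                ev.subtype.value,
                str(int(ev.vaf_validated)),
                str(int(ev.trans_assumed)),
                str(int(ev.ambiguous_subtype)),
                "" if vaf is None else repr(vaf),
                ";".join(h.evidence_pointer for h in ev.hits),
            ]) + "\n")


def read_events(path: PathLike) -> list[DoubleHitEvent]:
    """Read an events TSV back; hits come back as evidence-pointer stubs."""
    events: list[DoubleHitEvent] = []
    for lineno, row in _iter_rows(path, EVENTS_COLUMNS):
        try:
            subtype = EventSubtype(row["subtype"])
            pointers = row["evidence"].split(";") if row["evidence"] else []
            vaf = (float(row["germline_tumor_vaf"])
                   if row["germline_tumor_vaf"] else None)
            stubs = []
            for i, ptr in enumerate(pointers):
                if subtype in (EventSubtype.GERMLINE_PLUS_SOMATIC_MUTATION,
                               EventSubtype.GERMLINE_PLUS_ALLELE_LOSS) and i == 0:
                    hit_type, vaf_i = HitType.GERMLINE_PATHOGENIC, vaf
                elif "tcn=" in ptr:
                    hit_type, vaf_i = HitType.ALLELE_LOSS_SCNV, None
                else:
                    hit_type, vaf_i = HitType.SOMATIC_MUTATION, None
                cat = None
                if hit_type is HitType.ALLELE_LOSS_SCNV:
                    # recover the category from the tcn/lcn in the pointer
                    from .hit_classification import classify_allele_loss
                    cn = dict(kv.split("=") for kv in
                              ptr.rsplit(":", 1)[1].split(","))
                    lcn = None if cn["lcn"] == "NA" else int(cn["lcn"])
                    cat = classify_allele_loss(int(cn["tcn"]), lcn)
                stubs.append(Hit(row["sample_id"], row["gene_symbol"],
                                 hit_type, scnv_category=cat,
                                 evidence=ptr, tumor_vaf=vaf_i))
            events.append(DoubleHitEvent(
                sample_id=row["sample_id"],
                gene_symbol=row["gene_symbol"],
                event_class=EventClass(row["event_class"]),
                subtype=subtype,
                vaf_validated=bool(int(row["vaf_validated"])),
                hits=tuple(stubs),
                trans_assumed=bool(int(row["trans_assumed"])),
                ambiguous_subtype=bool(int(row["ambiguous_subtype"])),
            ))
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno) from None
    return events
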