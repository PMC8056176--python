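"""Synthetic cohorts with planted truth.

Emulates, without any external data, the inputs of a germline-predisposition
and double-hit study: a susceptibility-gene panel split into tumor
suppressors, oncogenes, and non-classified genes; rare pathogenic germline
carriers with per-gene case/control carrier-rate differentials; somatic
second hits (qualifying mutations and allele-loss copy-number segments)
planted on a fraction of germline carriers; purely somatic double hits;
decoy variants that the pathogenicity and rarity filters must remove; tumor
VAFs drawn from distinct "wild-type lost" and "wild-type retained"
components; and an age-at-diagnosis model in which carriers of
germline/somatic events are diagnosed younger.

Every stochastic draw flows from one integer-seeded generator, so a fixed
seed reproduces the emitted tables byte for byte.  The planted truth
(carriers, events with their drawn tumor VAFs, rates, age groups) is
returned alongside the tables and round-trips through JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from .cohort_model import (
    Assertion,
    ClinicalRecord,
    Consequence,
    CopyNumberSegment,
    FormatError,
    GeneClass,
    GenePanelEntry,
    GeneSet,
    Genotype,
    GermlineVariantRecord,
    PathLike,
    PolyPhen,
    ScnvCategory,
    Sift,
    SomaticMutationRecord,
    write_clinical,
    write_control_counts,
    write_gene_panel,
    write_germline_variants,
    write_gmt,
    write_segments,
    write_somatic_mutations,
)

TRUTH_VERSION = 1

_BASES = ("A", "C", "G", "T")

#: (tcn, lcn) states for each allele-loss category; duplication LOH draws
#: its total copy number separately
_LOSS_STATES = {
    ScnvCategory.HOMOZYGOUS_DELETION: (0, 0),
    ScnvCategory.HEMIZYGOUS_DELETION: (1, 0),
    ScnvCategory.COPY_NEUTRAL_LOH: (2, 0),
    ScnvCategory.DUPLICATION_LOH: (3, 0),
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class VafModel:
    """Beta components for the germline variant's tumor VAF.

    With the wild-type allele lost the variant allele dominates the tumor:
    mass concentrated above 0.5 (defaults Beta(12, 5), mean ~0.71, ~4% of
    draws below 0.5 — those planted events are exactly the ones the VAF
    check must remove).  With the wild-type allele retained the VAF sits
    near 0.5 with spread below (Beta(30, 30)).
    """

    lost_alpha: float = 12.0
    lost_beta: float = 5.0
    retained_alpha: float = 30.0
    retained_beta: float = 30.0


@dataclass
class AgeModel:
    """Normal age-at-diagnosis components (years), truncated to [min, max].

    Carriers of germline/somatic double-hit events are diagnosed younger
    (mean 54.6, SD 11.2) than carriers of somatic/somatic events (mean 60.6,
    SD 7.8); everyone else draws from a background near the cohort average.
    """

    background_mean: float = 58.8
    background_sd: float = 8.3
    germline_somatic_mean: float = 54.6
    germline_somatic_sd: float = 11.2
    somatic_somatic_mean: float = 60.6
    somatic_somatic_sd: float = 7.8
    min_age: float = 20.0
    max_age: float = 95.0


@dataclass
class NoiseModel:
    """Optional corruption switches, all off by default (noise-free)."""

    #: probability that a planted carrier's assertion is downgraded to uncertain
    assertion_error_rate: float = 0.0
    #: probability that a planted deleterious missense loses its SIFT vote
    predictor_discordance_rate: float = 0.0
    #: SD of Gaussian jitter added to population allele frequencies
    af_jitter_sd: float = 0.0


@dataclass
class SimConfig:
    """Study conditions of one simulated cohort.

    Defaults mirror the cohort the pipeline targets: 571 tumor cases against
    a 504-individual control population, a 260-gene panel (139 TSG / 36
    oncogene / 85 non-classified), a highlighted gene with case/control
    carrier rates 3.3% vs 0.79%, a background per-gene carrier rate chosen so
    roughly a quarter of cases carry >= 1 pathogenic variant, 16/143 of
    germline carriers in TSGs receiving a somatic second hit (2:14 mutation
    vs allele loss), and 68 purely somatic double hits (65 double mutations,
    3 mutation + allele loss).
    """

    seed: int = 0
    n_cases: int = 571
    n_controls: int = 504
    n_tsg: int = 139
    n_oncogene: int = 36
    n_non_classified: int = 85
    #: per-gene (case rate, control rate) overrides, keyed by gene symbol
    gene_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"TSG001": (0.033, 0.0079)})
    background_case_rate: float = 0.0011
    background_control_rate: float = 0.0008
    #: fraction of germline TSG carriers receiving a somatic second hit
    second_hit_fraction: float = 16 / 143
    #: (somatic mutation, allele loss) mix for germline second hits
    germline_subtype_mix: tuple[float, float] = (2 / 16, 14 / 16)
    #: number of somatic/somatic events planted across the cohort
    n_somatic_somatic: int = 68
    #: (mutation + allele loss, double mutation) mix for somatic/somatic events
    somatic_subtype_mix: tuple[float, float] = (3 / 68, 65 / 68)
    #: expected decoy germline variants per sample (benign or common-AF)
    decoy_germline_per_sample: float = 2.0
    #: expected qualifying singleton somatic hits per sample
    singleton_somatic_per_sample: float = 1.0
    #: expected non-qualifying somatic decoys per sample
    decoy_somatic_per_sample: float = 2.0
    #: expected stray allele-loss segments per sample (no mutation partner)
    stray_loss_per_sample: float = 0.5
    #: expected copy-number segments per sample that retain heterozygosity
    neutral_segments_per_sample: float = 2.0
    vaf: VafModel = field(default_factory=VafModel)
    age: AgeModel = field(default_factory=AgeModel)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        if min(self.n_tsg, self.n_oncogene, self.n_non_classified) < 0:
            raise ValueError("panel sizes must be non-negative")
        rates = [self.background_case_rate, self.background_control_rate,
                 self.second_hit_fraction,
                 *(r for pair in self.gene_rates.values() for r in pair)]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("rates and fractions must lie in [0, 1]")
        for mix in (self.germline_subtype_mix, self.somatic_subtype_mix):
            if abs(sum(mix) - 1.0) > 1e-9 or any(m < 0 for m in mix):
                raise ValueError(f"subtype mix {mix} must be a distribution")
        for sd in (self.age.background_sd, self.age.germline_somatic_sd,
                   self.age.somatic_somatic_sd):
            if sd <= 0:
                raise ValueError("age SDs must be positive")
        unknown = [g for g in self.gene_rates
                   if not self._symbol_known(g)]
        if unknown:
            raise ValueError(f"gene_rates refer to unknown genes {unknown}")

    def _symbol_known(self, symbol: str) -> bool:
        return symbol in {e.gene_symbol for e in build_panel(
            self.n_tsg, self.n_oncogene, self.n_non_classified)}


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEvent:
    sample_id: str
    gene_symbol: str
    subtype: str
    #: tumor VAF drawn for the germline variant (germline subtypes only)
    germline_tumor_vaf: Optional[float] = None


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    carriers: list[tuple[str, str, str]] = field(default_factory=list)
    events: list[PlantedEvent] = field(default_factory=list)
    gene_case_rates: dict[str, float] = field(default_factory=dict)
    gene_control_rates: dict[str, float] = field(default_factory=dict)
    age_groups: dict[str, str] = field(default_factory=dict)

    def expected_surviving_events(self, vaf_cutoff: float = 0.5,
                                  ) -> set[tuple[str, str, str]]:
        """Planted events that must survive the tumor-VAF validation.

        A germline+allele-loss event planted with tumor VAF strictly below
        the cutoff is expected to be removed; everything else survives.
        """
        out: set[tuple[str, str, str]] = set()
        for ev in self.events:
            if (ev.subtype == "germline_plus_allele_loss"
                    and ev.germline_tumor_vaf is not None
                    and ev.germline_tumor_vaf < vaf_cutoff):
                continue
            out.add((ev.sample_id, ev.gene_symbol, ev.subtype))
        return out


def write_truth(truth: SimTruth, path: PathLike) -> None:
    payload = {"version": TRUTH_VERSION,
               "carriers": [list(t) for t in truth.carriers],
               "events": [asdict(e) for e in truth.events],
               "gene_case_rates": truth.gene_case_rates,
               "gene_control_rates": truth.gene_control_rates,
               "age_groups": truth.age_groups}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True),
                          encoding="utf-8")


def read_truth(path: PathLike) -> SimTruth:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable truth file: {exc}", path) from None
    version = payload.get("version")
    if version != TRUTH_VERSION:
        raise FormatError(
            f"truth version {version!r} != supported {TRUTH_VERSION}", path)
    return SimTruth(
        carriers=[tuple(t) for t in payload["carriers"]],
        events=[PlantedEvent(**e) for e in payload["events"]],
        gene_case_rates=payload["gene_case_rates"],
        gene_control_rates=payload["gene_control_rates"],
        age_groups=payload["age_groups"],
    )


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------

def build_panel(n_tsg: int, n_oncogene: int,
                n_non_classified: int) -> list[GenePanelEntry]:
    """Deterministic synthetic gene panel with non-overlapping 100-kb loci.

    Genes are named TSG###, ONC###, NCG### and laid out round-robin over
    chr1..chr22 at 1-Mb spacing, so copy-number segments confined to one
    gene's interval can never touch another gene.
    """
    entries: list[GenePanelEntry] = []
    specs = [("TSG", GeneClass.TSG, n_tsg),
             ("ONC", GeneClass.ONCOGENE, n_oncogene),
             ("NCG", GeneClass.NON_CLASSIFIED, n_non_classified)]
    slot_on_chrom = {f"chr{i}": 0 for i in range(1, 23)}
    idx = 0
    for prefix, gene_class, count in specs:
        for i in range(1, count + 1):
            chrom = f"chr{(idx % 22) + 1}"
            slot = slot_on_chrom[chrom]
            slot_on_chrom[chrom] += 1
            start = 1 + slot * 1_000_000
            entries.append(GenePanelEntry(
                gene_symbol=f"{prefix}{i:03d}", gene_class=gene_class,
                chrom=chrom, start=start, end=start + 99_999))
            idx += 1
    return entries


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    panel: list[GenePanelEntry]
    germline: list[GermlineVariantRecord]
    somatic: list[SomaticMutationRecord]
    segments: list[CopyNumberSegment]
    clinical: list[ClinicalRecord]
    control_counts: dict[str, tuple[int, int]]
    gene_sets: list[GeneSet]
    truth: SimTruth

    def write(self, outdir: PathLike) -> dict[str, Path]:
        """Write every table plus the truth JSON; returns the paths."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "panel": out / "gene_panel.tsv",
            "germline": out / "germline_variants.tsv",
            "somatic": out / "somatic_mutations.tsv",
            "segments": out / "segments.tsv",
            "clinical": out / "clinical.tsv",
            "control_counts": out / "control_counts.tsv",
            "gene_sets": out / "gene_sets.gmt",
            "truth": out / "truth.json",
        }
        write_gene_panel(self.panel, paths["panel"])
        write_germline_variants(self.germline, paths["germline"])
        write_somatic_mutations(self.somatic, paths["somatic"])
        write_segments(self.segments, paths["segments"])
        write_clinical(self.clinical, paths["clinical"])
        write_control_counts(self.control_counts, paths["control_counts"])
        write_gmt(self.gene_sets, paths["gene_sets"])
        write_truth(self.truth, paths["truth"])
        return paths


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return _BASES[i], _BASES[j]


def _round6(x: float) -> float:
    return float(round(x, 6))


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort with planted truth.

    Deterministic under a fixed seed.  Planted lesions are coordinated so
    that on a noise-free configuration the downstream pipeline recovers the
    planted carriers and events exactly:

    * every (sample, gene) pair holding a planted hit is claimed, so stray
      singleton mutations and stray allele-loss segments can never combine
      into an unplanned event;
    * decoy germline variants carry benign/uncertain assertions or common
      allele frequencies, so the pathogenicity and rarity filters remove
      them;
    * decoy somatic mutations are synonymous or benign-predicted missense;
    * copy-number segments are confined to single-gene intervals.
    """
    rng = np.random.default_rng(config.seed)
    panel = build_panel(config.n_tsg, config.n_oncogene,
                        config.n_non_classified)
    by_symbol = {e.gene_symbol: e for e in panel}
    tsg_symbols = [e.gene_symbol for e in panel
                   if e.gene_class is GeneClass.TSG]
    samples = [f"CASE{i:04d}" for i in range(1, config.n_cases + 1)]

    truth = SimTruth()
    germline: list[GermlineVariantRecord] = []
    somatic: list[SomaticMutationRecord] = []
    segments: list[CopyNumberSegment] = []
    used_pairs: set[tuple[str, str]] = set()

    def case_rate(gene: str) -> float:
        return config.gene_rates.get(gene, (config.background_case_rate,))[0]

    def control_rate(gene: str) -> float:
        pair = config.gene_rates.get(gene)
        return pair[1] if pair else config.background_control_rate

    # -- germline carriers ---------------------------------------------------
    carrier_pairs: list[tuple[str, str]] = []
    for entry in panel:
        rate = case_rate(entry.gene_symbol)
        truth.gene_case_rates[entry.gene_symbol] = rate
        truth.gene_control_rates[entry.gene_symbol] = \
            control_rate(entry.gene_symbol)
        if config.n_cases == 0:
            continue
        mask = rng.random(config.n_cases) < rate
        for i in np.flatnonzero(mask):
            carrier_pairs.append((samples[i], entry.gene_symbol))
            used_pairs.add((samples[i], entry.gene_symbol))

    # -- second hits on germline TSG carriers --------------------------------
    carrier_vaf: dict[tuple[str, str], float] = {}
    v = config.vaf
    for sample_id, gene in carrier_pairs:
        entry = by_symbol[gene]
        planted_subtype: Optional[str] = None
        if (entry.gene_class is GeneClass.TSG
                and rng.random() < config.second_hit_fraction):
            planted_subtype = ("germline_plus_somatic_mutation"
                               if rng.random() < config.germline_subtype_mix[0]
                               else "germline_plus_allele_loss")
        if planted_subtype == "germline_plus_allele_loss":
            vaf = _round6(rng.beta(v.lost_alpha, v.lost_beta))
            segments.append(_loss_segment(rng, sample_id, entry))
        else:
            vaf = _round6(rng.beta(v.retained_alpha, v.retained_beta))
            if planted_subtype == "germline_plus_somatic_mutation":
                somatic.append(_qualifying_mutation(rng, sample_id, entry,
                                                    config))
        record = _germline_variant(rng, sample_id, entry, vaf, config)
        germline.append(record)
        carrier_vaf[(sample_id, gene)] = vaf
        truth.carriers.append((sample_id, gene, record.variant_id))
        if planted_subtype is not None:
            truth.events.append(PlantedEvent(sample_id, gene, planted_subtype,
                                             germline_tumor_vaf=vaf))

    # -- somatic/somatic events ----------------------------------------------
    if config.n_cases > 0 and tsg_symbols:
        planted = 0
        attempts = 0
        max_attempts = 50 * max(1, config.n_somatic_somatic)
        while planted < config.n_somatic_somatic and attempts < max_attempts:
            attempts += 1
            sample_id = samples[int(rng.integers(config.n_cases))]
            gene = tsg_symbols[int(rng.integers(len(tsg_symbols)))]
            if (sample_id, gene) in used_pairs:
                continue
            used_pairs.add((sample_id, gene))
            entry = by_symbol[gene]
            if rng.random() < config.somatic_subtype_mix[0]:
                subtype = "somatic_plus_allele_loss"
                somatic.append(_qualifying_mutation(rng, sample_id, entry,
                                                    config))
                segments.append(_loss_segment(rng, sample_id, entry))
            else:
                subtype = "double_somatic_mutation"
                m1 = _qualifying_mutation(rng, sample_id, entry, config)
                m2 = _qualifying_mutation(rng, sample_id, entry, config)
                while m2.pos == m1.pos:
                    m2 = _qualifying_mutation(rng, sample_id, entry, config)
                somatic.extend([m1, m2])
            truth.events.append(PlantedEvent(sample_id, gene, subtype))
            planted += 1

    # -- background lesions and decoys ---------------------------------------
    for sample_id in samples:
        # qualifying singleton somatic hits on unclaimed pairs
        for _ in range(rng.poisson(config.singleton_somatic_per_sample)):
            for _try in range(20):
                entry = panel[int(rng.integers(len(panel)))]
                if (sample_id, entry.gene_symbol) not in used_pairs:
                    used_pairs.add((sample_id, entry.gene_symbol))
                    somatic.append(_qualifying_mutation(rng, sample_id, entry,
                                                        config))
                    break
        # stray allele-loss segments with no mutation partner
        for _ in range(rng.poisson(config.stray_loss_per_sample)):
            for _try in range(20):
                entry = panel[int(rng.integers(len(panel)))]
                if (sample_id, entry.gene_symbol) not in used_pairs:
                    used_pairs.add((sample_id, entry.gene_symbol))
                    segments.append(_loss_segment(rng, sample_id, entry))
                    break
        # non-qualifying somatic decoys (safe anywhere)
        for _ in range(rng.poisson(config.decoy_somatic_per_sample)):
            entry = panel[int(rng.integers(len(panel)))]
            somatic.append(_decoy_mutation(rng, sample_id, entry))
        # heterozygosity-retaining segments (safe anywhere)
        for _ in range(rng.poisson(config.neutral_segments_per_sample)):
            entry = panel[int(rng.integers(len(panel)))]
            tcn, lcn = ((2, 1), (3, 1), (4, 2))[int(rng.integers(3))]
            segments.append(CopyNumberSegment(
                sample_id, entry.chrom, entry.start, entry.end, tcn, lcn))
        # decoy germline variants the filters must remove
        for _ in range(rng.poisson(config.decoy_germline_per_sample)):
            entry = panel[int(rng.integers(len(panel)))]
            germline.append(_decoy_germline(rng, sample_id, entry))

    # -- ages -----------------------------------------------------------------
    gs_samples = {e.sample_id for e in truth.events
                  if e.subtype.startswith("germline")}
    ss_samples = {e.sample_id for e in truth.events
                  if not e.subtype.startswith("germline")} - gs_samples
    a = config.age
    clinical: list[ClinicalRecord] = []
    for sample_id in samples:
        if sample_id in gs_samples:
            group, mean, sd = ("germline_somatic", a.germline_somatic_mean,
                               a.germline_somatic_sd)
        elif sample_id in ss_samples:
            group, mean, sd = ("somatic_somatic", a.somatic_somatic_mean,
                               a.somatic_somatic_sd)
        else:
            group, mean, sd = ("background", a.background_mean,
                               a.background_sd)
        age = _round6(_truncnorm(rng, mean, sd, a.min_age, a.max_age, 1)[0])
        truth.age_groups[sample_id] = group
        clinical.append(ClinicalRecord(sample_id=sample_id,
                                       age_at_diagnosis=age,
                                       sex=("F", "M")[int(rng.integers(2))],
                                       cohort_label="case"))

    # -- control carrier counts ----------------------------------------------
    control_counts = {
        e.gene_symbol: (int(rng.binomial(config.n_controls,
                                         control_rate(e.gene_symbol))),
                        config.n_controls)
        for e in panel
    }

    # -- gene sets -------------------------------------------------------------
    gene_sets = _build_gene_sets(rng, panel, config)

    return SimulatedCohort(panel=panel, germline=germline, somatic=somatic,
                           segments=segments, clinical=clinical,
                           control_counts=control_counts,
                           gene_sets=gene_sets, truth=truth)


# -- lesion builders ---------------------------------------------------------

def _germline_variant(rng: np.random.Generator, sample_id: str,
                      entry: GenePanelEntry, tumor_vaf: float,
                      config: SimConfig) -> GermlineVariantRecord:
    noise = config.noise
    assertion = (Assertion.PATHOGENIC, Assertion.LIKELY_PATHOGENIC)[
        int(rng.integers(2))]
    if noise.assertion_error_rate > 0 and rng.random() < noise.assertion_error_rate:
        assertion = Assertion.UNCERTAIN
    af = rng.uniform(0.0, 0.005)
    if noise.af_jitter_sd > 0:
        af = min(1.0, max(0.0, af + rng.normal(0.0, noise.af_jitter_sd)))
    ref, alt = _snv_alleles(rng)
    return GermlineVariantRecord(
        sample_id=sample_id, gene_symbol=entry.gene_symbol, chrom=entry.chrom,
        pos=int(rng.integers(entry.start, entry.end + 1)), ref=ref, alt=alt,
        consequence=(Consequence.MISSENSE, Consequence.FRAMESHIFT,
                     Consequence.NONSENSE, Consequence.SPLICE_SITE)[
                         int(rng.integers(4))],
        assertion=assertion,
        pop_afs={"gnomad": _round6(af)},
        genotype=Genotype.HOM if rng.random() < 0.02 else Genotype.HET,
        tumor_vaf=tumor_vaf,
    )


def _decoy_germline(rng: np.random.Generator, sample_id: str,
                    entry: GenePanelEntry) -> GermlineVariantRecord:
    ref, alt = _snv_alleles(rng)
    if rng.random() < 0.5:
        # non-pathogenic assertion, rare
        assertion = (Assertion.BENIGN, Assertion.LIKELY_BENIGN,
                     Assertion.UNCERTAIN, Assertion.NONE)[int(rng.integers(4))]
        af = rng.uniform(0.0, 0.005)
    else:
        # pathogenic assertion but common in the population
        assertion = Assertion.PATHOGENIC
        af = rng.uniform(0.01, 0.1)
    return GermlineVariantRecord(
        sample_id=sample_id, gene_symbol=entry.gene_symbol, chrom=entry.chrom,
        pos=int(rng.integers(entry.start, entry.end + 1)), ref=ref, alt=alt,
        consequence=Consequence.MISSENSE, assertion=assertion,
        pop_afs={"gnomad": _round6(af)}, genotype=Genotype.HET,
        tumor_vaf=_round6(rng.beta(30, 30)),
    )


def _qualifying_mutation(rng: np.random.Generator, sample_id: str,
                         entry: GenePanelEntry,
                         config: SimConfig) -> SomaticMutationRecord:
    ref, alt = _snv_alleles(rng)
    consequence = (Consequence.FRAMESHIFT, Consequence.NONSENSE,
                   Consequence.SPLICE_SITE, Consequence.MISSENSE)[
                       int(rng.integers(4))]
    sift, polyphen, cadd = Sift.ABSENT, PolyPhen.ABSENT, None
    if consequence is Consequence.MISSENSE:
        sift = Sift.D
        polyphen = (PolyPhen.D, PolyPhen.P)[int(rng.integers(2))]
        cadd = _round6(rng.uniform(16.0, 40.0))
        if (config.noise.predictor_discordance_rate > 0
                and rng.random() < config.noise.predictor_discordance_rate):
            sift = Sift.T
    return SomaticMutationRecord(
        sample_id=sample_id, gene_symbol=entry.gene_symbol, chrom=entry.chrom,
        pos=int(rng.integers(entry.start, entry.end + 1)), ref=ref, alt=alt,
        consequence=consequence,
        protein_pos=int(rng.integers(1, 1000)),
        sift=sift, polyphen=polyphen, cadd=cadd,
        tumor_vaf=_round6(rng.uniform(0.1, 0.6)),
    )


def _decoy_mutation(rng: np.random.Generator, sample_id: str,
                    entry: GenePanelEntry) -> SomaticMutationRecord:
    ref, alt = _snv_alleles(rng)
    if rng.random() < 0.5:
        consequence, sift, polyphen, cadd = (
            Consequence.SYNONYMOUS, Sift.ABSENT, PolyPhen.ABSENT, None)
    else:
        # benign-predicted missense: zero damaging votes
        consequence = Consequence.MISSENSE
        sift, polyphen = Sift.T, PolyPhen.B
        cadd = _round6(rng.uniform(0.0, 12.0))
    return SomaticMutationRecord(
        sample_id=sample_id, gene_symbol=entry.gene_symbol, chrom=entry.chrom,
        pos=int(rng.integers(entry.start, entry.end + 1)), ref=ref, alt=alt,
        consequence=consequence,
        protein_pos=int(rng.integers(1, 1000)),
        sift=sift, polyphen=polyphen, cadd=cadd,
        tumor_vaf=_round6(rng.uniform(0.05, 0.5)),
    )


def _loss_segment(rng: np.random.Generator, sample_id: str,
                  entry: GenePanelEntry) -> CopyNumberSegment:
    category = list(_LOSS_STATES)[int(rng.integers(4))]
    tcn, lcn = _LOSS_STATES[category]
    if category is ScnvCategory.DUPLICATION_LOH:
        tcn = int(rng.integers(3, 6))
    return CopyNumberSegment(sample_id, entry.chrom, entry.start, entry.end,
                             tcn=tcn, lcn=lcn)


def _build_gene_sets(rng: np.random.Generator,
                     panel: list[GenePanelEntry],
                     config: SimConfig) -> list[GeneSet]:
    symbols = [e.gene_symbol for e in panel]
    tsg = [e.gene_symbol for e in panel if e.gene_class is GeneClass.TSG]
    sets: list[GeneSet] = []
    if tsg:
        # one repair-pathway-like set concentrated on the highlighted genes
        core = sorted(config.gene_rates) + list(
            rng.choice([g for g in tsg if g not in config.gene_rates],
                       size=min(11, max(0, len(tsg) - len(config.gene_rates))),
                       replace=False))
        sets.append(GeneSet("PATHWAY_DNA_REPAIR", frozenset(core)))
    for i in range(1, 5):
        size = min(len(symbols), 15)
        if size == 0:
            break
        members = rng.choice(symbols, size=size, replace=False)
        sets.append(GeneSet(f"PATHWAY_RANDOM_{i}", frozenset(members)))
    return sets
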