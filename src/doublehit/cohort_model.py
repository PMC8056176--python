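"""Domain types, tab-delimited readers/writers, and sample-level QC.

All tables are UTF-8, tab-delimited text; lines starting with ``#`` are
ignored.  Genomic coordinates are 1-based and inclusive at both ends
(VCF/SEG convention) in every type and every file read or written here.
Missing optional values are written as empty cells (or ``NA`` for the
minor copy number) and parse as ``None`` — never as zero, because an
unknown allele frequency and an allele frequency of zero behave
differently downstream.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence, Union

logger = logging.getLogger("doublehit")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input table violates the expected dialect or a type invariant."""

    def __init__(self, message: str, path: Optional[PathLike] = None,
                 line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

class GeneClass(str, enum.Enum):
    TSG = "TSG"
    ONCOGENE = "oncogene"
    NON_CLASSIFIED = "non_classified"


class Assertion(str, enum.Enum):
    """Curated clinical-significance label attached to a germline variant."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    NONE = "none"


class Genotype(str, enum.Enum):
    HET = "het"
    HOM = "hom"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Mapping from common MAF ``Variant_Classification`` and Sequence-Ontology /
#: VEP terms onto the controlled consequence vocabulary.  Annotated inputs may
#: use either dialect; anything already in the controlled vocabulary passes
#: through unchanged.
CONSEQUENCE_ALIASES: dict[str, Consequence] = {
    # MAF Variant_Classification
    "Missense_Mutation": Consequence.MISSENSE,
    "Frame_Shift_Del": Consequence.FRAMESHIFT,
    "Frame_Shift_Ins": Consequence.FRAMESHIFT,
    "Nonsense_Mutation": Consequence.NONSENSE,
    "Splice_Site": Consequence.SPLICE_SITE,
    "In_Frame_Del": Consequence.INFRAME_INDEL,
    "In_Frame_Ins": Consequence.INFRAME_INDEL,
    "Silent": Consequence.SYNONYMOUS,
    "Nonstop_Mutation": Consequence.OTHER,
    "Translation_Start_Site": Consequence.OTHER,
    "3'UTR": Consequence.OTHER,
    "5'UTR": Consequence.OTHER,
    "Intron": Consequence.OTHER,
    # Sequence Ontology / VEP
    "missense_variant": Consequence.MISSENSE,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "stop_gained": Consequence.NONSENSE,
    "splice_acceptor_variant": Consequence.SPLICE_SITE,
    "splice_donor_variant": Consequence.SPLICE_SITE,
    "splice_region_variant": Consequence.SPLICE_SITE,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "stop_lost": Consequence.OTHER,
    "start_lost": Consequence.OTHER,
}


def normalize_consequence(term: str) -> Consequence:
    """Map a raw annotation term onto the controlled consequence vocabulary.

    Accepts controlled terms verbatim plus the MAF and SO/VEP aliases in
    :data:`CONSEQUENCE_ALIASES`; anything else raises ``ValueError``.
    """
    try:
        return Consequence(term)
    except ValueError:
        pass
    if term in CONSEQUENCE_ALIASES:
        return CONSEQUENCE_ALIASES[term]
    raise ValueError(f"unknown consequence term {term!r}")


class Sift(str, enum.Enum):
    D = "D"          # deleterious
    T = "T"          # tolerated
    ABSENT = "absent"


class PolyPhen(str, enum.Enum):
    D = "D"          # probably damaging
    P = "P"          # possibly damaging
    B = "B"          # benign
    ABSENT = "absent"


class ScnvCategory(str, enum.Enum):
    """Somatic copy-number states implying loss of one parental allele."""

    HOMOZYGOUS_DELETION = "homozygous_deletion"
    HEMIZYGOUS_DELETION = "hemizygous_deletion"
    COPY_NEUTRAL_LOH = "copy_neutral_loh"
    DUPLICATION_LOH = "duplication_loh"


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

def _check_fraction(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class GenePanelEntry:
    """One gene of the susceptibility-gene panel with its class and interval."""

    gene_symbol: str
    gene_class: GeneClass
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_symbol}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene_symbol}: coordinates are 1-based")


@dataclass(frozen=True)
class GermlineVariantRecord:
    """One annotated germline variant observed in one sample."""

    sample_id: str
    gene_symbol: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    assertion: Assertion
    pop_afs: Mapping[str, float] = field(default_factory=dict)
    genotype: Genotype = Genotype.HET
    tumor_vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for pop, af in self.pop_afs.items():
            _check_fraction(f"pop_afs[{pop}]", af)
        _check_fraction("tumor_vaf", self.tumor_vaf)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SomaticMutationRecord:
    """One somatic mutation with in-silico predictor annotations."""

    sample_id: str
    gene_symbol: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    protein_pos: Optional[int] = None
    sift: Sift = Sift.ABSENT
    polyphen: PolyPhen = PolyPhen.ABSENT
    cadd: Optional[float] = None
    tumor_vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.protein_pos is not None and self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")
        _check_fraction("tumor_vaf", self.tumor_vaf)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CopyNumberSegment:
    """Allele-specific copy-number interval: total (tcn) and minor (lcn) copies."""

    sample_id: str
    chrom: str
    start: int
    end: int
    tcn: int
    lcn: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.tcn < 0:
            raise ValueError(f"negative total copy number {self.tcn}")
        if self.lcn is not None:
            if self.lcn < 0:
                raise ValueError(f"negative minor copy number {self.lcn}")
            if 2 * self.lcn > self.tcn:
                raise ValueError(
                    f"minor copy number {self.lcn} exceeds half of total {self.tcn}")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    age_at_diagnosis: Optional[float] = None
    sex: Optional[str] = None
    cohort_label: str = ""

    def __post_init__(self) -> None:
        age = self.age_at_diagnosis
        if age is not None and not (0.0 <= age <= 120.0):
            raise ValueError(f"age {age} outside [0, 120]")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _open(path: PathLike, mode: str = "r") -> IO[str]:
    return open(path, mode, encoding="utf-8", newline="")


def _iter_rows(path: PathLike, required: Sequence[str]) -> Iterator[tuple[int, dict[str, str]]]:
    """Yield (line_number, column->cell) for each data row of a TSV file.

    Skips '#' comment lines and blank lines; validates that every required
    column is present in the header.
    """
    with _open(path) as fh:
        header: Optional[list[str]] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                missing = [c for c in required if c not in header]
                if missing:
                    raise FormatError(
                        f"missing required column(s) {missing}", path, lineno)
                continue
            if len(cells) != len(header):
                raise FormatError(
                    f"expected {len(header)} fields, found {len(cells)}",
                    path, lineno)
            yield lineno, dict(zip(header, cells))
    if header is None:
        raise FormatError("empty file (no header)", path)


def _opt_str(cell: str) -> Optional[str]:
    return cell if cell not in ("", "NA", ".") else None


def _parse_int(cell: str, what: str, path: PathLike, lineno: int) -> int:
    try:
        return int(cell)
    except ValueError:
        raise FormatError(f"non-integer {what} {cell!r}", path, lineno) from None


def _parse_float(cell: str, what: str, path: PathLike, lineno: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"non-numeric {what} {cell!r}", path, lineno) from None


def _wrap_invariant(builder, path: PathLike, lineno: int):
    try:
        return builder()
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(str(exc), path, lineno) from None


# -- gene panel -------------------------------------------------------------

PANEL_COLUMNS = ("gene", "class", "chrom", "start", "end")


def read_gene_panel(path: PathLike) -> list[GenePanelEntry]:
    """Read a gene-panel TSV (columns: gene, class, chrom, start, end).

    Order is preserved; duplicate gene symbols and unknown class tokens are
    format errors naming the offending line.
    """
    entries: list[GenePanelEntry] = []
    seen: set[str] = set()
    for lineno, row in _iter_rows(path, PANEL_COLUMNS):
        symbol = row["gene"]
        if symbol in seen:
            raise FormatError(f"duplicate gene {symbol!r}", path, lineno)
        seen.add(symbol)
        try:
            gene_class = GeneClass(row["class"])
        except ValueError:
            raise FormatError(
                f"unknown gene class {row['class']!r}", path, lineno) from None
        entry = _wrap_invariant(
            lambda: GenePanelEntry(
                gene_symbol=symbol,
                gene_class=gene_class,
                chrom=row["chrom"],
                start=_parse_int(row["start"], "start", path, lineno),
                end=_parse_int(row["end"], "end", path, lineno),
            ), path, lineno)
        entries.append(entry)
    return entries


def write_gene_panel(entries: Iterable[GenePanelEntry], path: PathLike) -> None:
    with _open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for e in entries:
            fh.write(f"{e.gene_symbol}\t{e.gene_class.value}\t{e.chrom}\t"
                     f"{e.start}\t{e.end}\n")


# -- copy-number segments ---------------------------------------------------

SEGMENT_COLUMNS = ("sample", "chrom", "start", "end", "tcn", "lcn")


def read_segments(path: PathLike) -> list[CopyNumberSegment]:
    """Read a SEG-like TSV of allele-specific copy-number intervals.

    ``lcn`` may be ``NA`` (minor copy number not estimated), parsed as absent.
    """
    segments: list[CopyNumberSegment] = []
    for lineno, row in _iter_rows(path, SEGMENT_COLUMNS):
        lcn_cell = _opt_str(row["lcn"])
        seg = _wrap_invariant(
            lambda: CopyNumberSegment(
                sample_id=row["sample"],
                chrom=row["chrom"],
                start=_parse_int(row["start"], "start", path, lineno),
                end=_parse_int(row["end"], "end", path, lineno),
                tcn=_parse_int(row["tcn"], "tcn", path, lineno),
                lcn=None if lcn_cell is None
                else _parse_int(lcn_cell, "lcn", path, lineno),
            ), path, lineno)
        segments.append(seg)
    return segments


def write_segments(segments: Iterable[CopyNumberSegment], path: PathLike) -> None:
    with _open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in segments:
            lcn = "NA" if s.lcn is None else str(s.lcn)
            fh.write(f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.tcn}\t{lcn}\n")


# -- germline variants ------------------------------------------------------

GERMLINE_COLUMNS = ("sample_id", "gene_symbol", "chrom", "pos", "ref", "alt",
                    "consequence", "assertion", "genotype", "tumor_vaf")


def read_germline_variants(path: PathLike) -> list[GermlineVariantRecord]:
    """Read a germline-variant TSV.

    Scalar fields use the type's field names as column headers; population
    allele frequencies are carried in any number of ``af_<population>``
    columns (empty cell = frequency unobserved in that population).
    """
    records: list[GermlineVariantRecord] = []
    for lineno, row in _iter_rows(path, GERMLINE_COLUMNS):
        pop_afs: dict[str, float] = {}
        for col, cell in row.items():
            if col.startswith("af_") and _opt_str(cell) is not None:
                pop_afs[col[3:]] = _parse_float(cell, col, path, lineno)
        vaf_cell = _opt_str(row["tumor_vaf"])
        try:
            consequence = normalize_consequence(row["consequence"])
            assertion = Assertion(row["assertion"])
            genotype = Genotype(row["genotype"])
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno) from None
        rec = _wrap_invariant(
            lambda: GermlineVariantRecord(
                sample_id=row["sample_id"],
                gene_symbol=row["gene_symbol"],
                chrom=row["chrom"],
                pos=_parse_int(row["pos"], "pos", path, lineno),
                ref=row["ref"],
                alt=row["alt"],
                consequence=consequence,
                assertion=assertion,
                pop_afs=pop_afs,
                genotype=genotype,
                tumor_vaf=None if vaf_cell is None
                else _parse_float(vaf_cell, "tumor_vaf", path, lineno),
            ), path, lineno)
        records.append(rec)
    return records


def write_germline_variants(records: Sequence[GermlineVariantRecord],
                            path: PathLike) -> None:
    pops = sorted({p for r in records for p in r.pop_afs})
    header = list(GERMLINE_COLUMNS) + [f"af_{p}" for p in pops]
    with _open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            cells = [r.sample_id, r.gene_symbol, r.chrom, str(r.pos), r.ref,
                     r.alt, r.consequence.value, r.assertion.value,
                     r.genotype.value,
                     "" if r.tumor_vaf is None else repr(r.tumor_vaf)]
            cells += ["" if p not in r.pop_afs else repr(r.pop_afs[p])
                      for p in pops]
            fh.write("\t".join(cells) + "\n")


# -- somatic mutations ------------------------------------------------------

SOMATIC_COLUMNS = ("sample_id", "gene_symbol", "chrom", "pos", "ref", "alt",
                   "consequence", "protein_pos", "sift", "polyphen", "cadd",
                   "tumor_vaf")


def read_somatic_mutations(path: PathLike) -> list[SomaticMutationRecord]:
    records: list[SomaticMutationRecord] = []
    for lineno, row in _iter_rows(path, SOMATIC_COLUMNS):
        ppos = _opt_str(row["protein_pos"])
        cadd = _opt_str(row["cadd"])
        vaf = _opt_str(row["tumor_vaf"])
        try:
            consequence = normalize_consequence(row["consequence"])
            sift = Sift(_opt_str(row["sift"]) or "absent")
            polyphen = PolyPhen(_opt_str(row["polyphen"]) or "absent")
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno) from None
        rec = _wrap_invariant(
            lambda: SomaticMutationRecord(
                sample_id=row["sample_id"],
                gene_symbol=row["gene_symbol"],
                chrom=row["chrom"],
                pos=_parse_int(row["pos"], "pos", path, lineno),
                ref=row["ref"],
                alt=row["alt"],
                consequence=consequence,
                protein_pos=None if ppos is None
                else _parse_int(ppos, "protein_pos", path, lineno),
                sift=sift,
                polyphen=polyphen,
                cadd=None if cadd is None
                else _parse_float(cadd, "cadd", path, lineno),
                tumor_vaf=None if vaf is None
                else _parse_float(vaf, "tumor_vaf", path, lineno),
            ), path, lineno)
        records.append(rec)
    return records


def write_somatic_mutations(records: Iterable[SomaticMutationRecord],
                            path: PathLike) -> None:
    with _open(path, "w") as fh:
        fh.write("\t".join(SOMATIC_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                r.sample_id, r.gene_symbol, r.chrom, str(r.pos), r.ref, r.alt,
                r.consequence.value,
                "" if r.protein_pos is None else str(r.protein_pos),
                "" if r.sift is Sift.ABSENT else r.sift.value,
                "" if r.polyphen is PolyPhen.ABSENT else r.polyphen.value,
                "" if r.cadd is None else repr(r.cadd),
                "" if r.tumor_vaf is None else repr(r.tumor_vaf),
            ]) + "\n")


# -- clinical ---------------------------------------------------------------

CLINICAL_COLUMNS = ("sample_id", "age_at_diagnosis", "sex", "cohort_label")


def read_clinical(path: PathLike) -> list[ClinicalRecord]:
    records: list[ClinicalRecord] = []
    for lineno, row in _iter_rows(path, CLINICAL_COLUMNS):
        age = _opt_str(row["age_at_diagnosis"])
        rec = _wrap_invariant(
            lambda: ClinicalRecord(
                sample_id=row["sample_id"],
                age_at_diagnosis=None if age is None
                else _parse_float(age, "age", path, lineno),
                sex=_opt_str(row["sex"]),
                cohort_label=row["cohort_label"],
            ), path, lineno)
        records.append(rec)
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: PathLike) -> None:
    with _open(path, "w") as fh:
        fh.write("\t".join(CLINICAL_COLUMNS) + "\n")
        for r in records:
            age = "" if r.age_at_diagnosis is None else repr(r.age_at_diagnosis)
            fh.write(f"{r.sample_id}\t{age}\t{r.sex or ''}\t{r.cohort_label}\n")


# -- GMT gene sets ----------------------------------------------------------

def read_gmt(path: PathLike) -> list[GeneSet]:
    """Read gene sets from standard GMT (name, description, members...)."""
    sets: list[GeneSet] = []
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line has {len(fields)} fields, need >= 3", path, lineno)
            name, _desc, *members = fields
            members = [m for m in members if m]
            unique = frozenset(members)
            if len(unique) < len(members):
                logger.warning("gene set %s (%s line %d): duplicate members "
                               "deduplicated", name, path, lineno)
            sets.append(_wrap_invariant(
                lambda: GeneSet(name=name, members=unique), path, lineno))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: PathLike,
              description: str = "na") -> None:
    with _open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# Sample-level QC
# ---------------------------------------------------------------------------

def sample_qc(sample_variant_counts: Mapping[str, int],
              min_variants: int = 80_000) -> dict[str, bool]:
    """Per-sample pass/fail on germline variant yield.

    A sample fails iff its joint-called variant count is strictly below
    ``min_variants`` (default 80,000) — low yield indicates poor sequencing
    quality; a count exactly at the threshold passes.
    """
    result: dict[str, bool] = {}
    for sample, count in sample_variant_counts.items():
        if count < 0:
            raise ValueError(f"negative variant count for {sample}: {count}")
        result[sample] = count >= min_variants
    return result


def hypermutant_filter(somatic_counts: Mapping[str, int],
                       max_mutations: Optional[int] = None) -> dict[str, bool]:
    """Optional hypermutant-sample exclusion.

    ``max_mutations=None`` (the default) disables the filter: every sample
    passes.  When set, samples with strictly more somatic mutations than the
    cutoff fail.
    """
    if max_mutations is None:
        return {s: True for s in somatic_counts}
    for sample, count in somatic_counts.items():
        if count < 0:
            raise ValueError(f"negative mutation count for {sample}: {count}")
    return {s: c <= max_mutations for s, c in somatic_counts.items()}


# -- control carrier counts -------------------------------------------------

CONTROL_COUNT_COLUMNS = ("gene", "carriers", "n")


def read_control_counts(path: PathLike) -> dict[str, tuple[int, int]]:
    """Read per-gene control-population carrier counts (gene, carriers, n)."""
    counts: dict[str, tuple[int, int]] = {}
    for lineno, row in _iter_rows(path, CONTROL_COUNT_COLUMNS):
        gene = row["gene"]
        if gene in counts:
            raise FormatError(f"duplicate gene {gene!r}", path, lineno)
        carriers = _parse_int(row["carriers"], "carriers", path, lineno)
        n = _parse_int(row["n"], "n", path, lineno)
        if not (0 <= carriers <= n):
            raise FormatError(
                f"carriers {carriers} outside [0, n={n}]", path, lineno)
        counts[gene] = (carriers, n)
    return counts


def write_control_counts(counts: Mapping[str, tuple[int, int]],
                         path: PathLike) -> None:
    with _open(path, "w") as fh:
        fh.write("\t".join(CONTROL_COUNT_COLUMNS) + "\n")
        for gene in sorted(counts):
            carriers, n = counts[gene]
            fh.write(f"{gene}\t{carriers}\t{n}\n")


# -- optional VCF ingestion -------------------------------------------------

#: default mapping of VCF INFO keys onto germline-record fields
DEFAULT_VCF_INFO_MAP = {
    "gene_symbol": "GENE",
    "consequence": "CSQ_CLASS",
    "assertion": "CLNSIG",
    "tumor_vaf": "TVAF",
    # any INFO key matching af_<population> is collected automatically
}


def read_germline_vcf(path: PathLike,
                      info_map: Optional[Mapping[str, str]] = None,
                      af_prefix: str = "AF_") -> list[GermlineVariantRecord]:
    """Read germline variants from an annotated (multi-sample) VCF.

    A thin adapter over :mod:`cyvcf2`: each non-reference genotype becomes
    one record.  ``info_map`` names the INFO keys carrying the gene symbol,
    consequence term, clinical assertion, and tumor VAF; INFO keys starting
    with ``af_prefix`` are collected as population allele frequencies
    (lower-cased population label).  Missing INFO entries parse as absent.
    """
    from cyvcf2 import VCF  # imported lazily: VCF input is optional

    keys = dict(DEFAULT_VCF_INFO_MAP)
    if info_map:
        keys.update(info_map)
    records: list[GermlineVariantRecord] = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for variant in vcf:
        info = dict(variant.INFO)
        gene = info.get(keys["gene_symbol"])
        if gene is None:
            continue
        pop_afs = {k[len(af_prefix):].lower(): float(v)
                   for k, v in info.items() if k.startswith(af_prefix)}
        raw_sig = str(info.get(keys["assertion"], "none")).lower()
        try:
            assertion = Assertion(raw_sig)
        except ValueError:
            assertion = Assertion.NONE
        consequence = normalize_consequence(
            str(info.get(keys["consequence"], "other")))
        tvaf = info.get(keys["tumor_vaf"])
        for sample, gt in zip(samples, variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            n_alt = sum(1 for a in alleles if a > 0)
            if n_alt == 0:
                continue
            records.append(GermlineVariantRecord(
                sample_id=sample,
                gene_symbol=str(gene),
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=variant.ALT[0] if variant.ALT else "*",
                consequence=consequence,
                assertion=assertion,
                pop_afs=pop_afs,
                genotype=Genotype.HOM if n_alt == len(alleles)
                else Genotype.HET,
                tumor_vaf=None if tvaf is None else float(tvaf),
            ))
    return records
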