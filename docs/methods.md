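# Methods

## The problem

Esophageal squamous cell carcinoma (ESCC), like several other solid tumors,
shows a measurable contribution of rare germline predisposition: a fraction
of patients carry a pathogenic or likely-pathogenic variant in a cancer
susceptibility gene (CSG), and under the two-hit model a tumor-suppressor
gene (TSG) drives tumorigenesis only when its second allele is also lost —
by a second mutation or by an allele-loss copy-number event.  This package
implements that analysis as a reusable pipeline: hit classification,
biallelic ("double-hit") event calling with tumor-VAF validation, exact
case-control association, carrier burden testing, an age comparison, and
gene-set over-representation, together with a synthetic-cohort simulator
that plants a known truth so every stage can be tested end to end without
access to protected sequencing data.

## Hit definitions

A *hit* is one inactivating lesion in one gene in one sample.

**Germline pathogenic hit.**  A germline variant counts when (i) its curated
clinical assertion is `pathogenic` or `likely_pathogenic` (assertions are
consumed, not computed — upstream annotation such as ClinVar/InterVar is out
of scope), (ii) it is rare: the maximum allele frequency over all supplied
population columns is at most 0.5% (inclusive), and (iii) the gene is on the
panel.  A variant absent from every frequency database passes the rarity
filter — an unobserved variant cannot exceed 0.5%.  Taking the maximum
across populations is the conservative choice when several databases are
supplied.  Het and hom genotypes both count once.

**Somatic mutation hit.**  Truncating classes (frameshift, nonsense,
splice-site, as annotated — no distance-to-junction recomputation) qualify
automatically.  Missense variants qualify when at least 2 of 3 in-silico
predictors call them damaging: SIFT `D`, PolyPhen-2 HDIV `D` or `P`, CADD
strictly above 15.  An absent annotation never votes.  In-frame indels have
no SIFT/PolyPhen output, so the 2-of-3 rule is ill-posed for them; by
default they qualify on CADD > 15 alone (`inframe_rule="cadd_only"`), and a
stricter `two_votes` mode subjects them to the full vote, which excludes
essentially all of them.

**Allele-loss SCNV hit.**  From allele-specific copy number (total `tcn`,
minor `lcn`): `tcn=0` homozygous deletion; `tcn=1` hemizygous deletion;
`tcn=2, lcn=0` copy-neutral LOH; `tcn>=3, lcn=0` duplication LOH.  A
retained minor allele (`lcn>=1`), or an unknown minor copy number at
`tcn>=2`, is not allele loss.  A gene takes the state of any allele-loss
segment overlapping its interval by at least one base; when several
overlap, deeper losses win (homozygous > hemizygous > copy-neutral LOH >
duplication LOH).  One allele-loss hit is emitted per (sample, gene).

A helper `proximity_match` supports the catalog cross-check used for
germline variants: true when a catalogued somatic mutation lies at the same
or a nearby (within five) amino-acid position.

## Double-hit calling

Events are called per (sample, gene), for TSGs only, with at most one event
per pair.  Eligible combinations, in priority order when several coexist:

1. germline + somatic mutation (`germline_plus_somatic_mutation`)
2. germline + allele loss (`germline_plus_allele_loss`)
3. somatic mutation + allele loss (`somatic_plus_allele_loss`)
4. two somatic mutations (`double_somatic_mutation`)

Classes: the first two are germline/somatic events, the last two
somatic/somatic.  Design choices that were genuinely open:

* *Priority when a germline hit co-occurs with both a somatic mutation and
  an allele loss*: the mutation wins — point-mutation evidence is more
  specific than a broad copy-number segment, and the resulting event needs
  no VAF validation.  Such events carry `ambiguous_subtype=True` so users
  can audit the choice.
* *Two germline hits alone* (candidate compound heterozygotes) form no
  event — the taxonomy has no germline/germline class — but are written to
  a side report rather than discarded.
* *Two allele-loss states alone* form no event: a copy-number hit only
  counts alongside a mutation.
* *Double somatic mutations are assumed in trans*; no phasing is attempted,
  and events carry `trans_assumed=True`.

**VAF validation.**  For a germline + allele-loss event, if the wild-type
allele was truly lost the germline variant should be enriched in the tumor,
so its tumor VAF should be at least 0.5.  Events with tumor VAF strictly
below 0.5 are removed; exactly 0.5 keeps.  A missing VAF keeps the event
with a logged warning by default (`missing="remove"` available).  Inputs
are assumed purity-corrected upstream; no depth-ratio check is attempted.

## Statistics

**Exact 2x2 inference.**  Carrier tables (case carriers/non-carriers vs
control carriers/non-carriers) are tested with Fisher's exact test.  The
two-sided p sums the probabilities of all tables with the observed margins
that are no more likely than the observed one, with a relative tie
tolerance of 1e-7 (the convention of mainstream implementations); the
summation is implemented in the package and is property-tested against
exact rational enumeration.  The reported odds ratio is the **conditional
maximum-likelihood estimate**: the odds parameter under which the expected
carrier count of Fisher's noncentral hypergeometric distribution equals the
observed count, with the exact 95% interval solving the 0.025
tail-probability equations (delegated to
`scipy.stats.contingency.odds_ratio`; tests verify the defining equation to
1e-8 and the tails to 1e-6).  This is the estimator exact-test software
reports, which is why a zero control-carrier cell yields an infinite point
estimate with a finite lower bound, and why estimates sit slightly below
the cross-product ratio `ad/bc` (also reported).  When an entire carrier
margin is empty the odds parameter is unidentifiable: the point estimate is
NaN and the interval degenerates to (0, inf).

**Carrier burden.**  A collapsing test: each individual is carrier or
non-carrier per gene, and the one-sided (enrichment in cases) exact
hypergeometric tail of the 2x2 table is reported.  Published burden
p-values from external tools are not reproducible from described inputs,
so these p-values are a method choice, not a benchmark.

**Age comparison.**  Pooled-variance two-sided Student's t on
age-at-diagnosis, germline/somatic vs somatic/somatic event carriers, with
a Welch option.  A patient carrying both event classes has a pathogenic
germline variant and goes to the germline/somatic group.

**Expression percentiles.** `ecdf_percentile` = 100 x (reference values
<= x)/n.

**Over-representation.**  One-sided hypergeometric upper tail per gene set
(over-representation is directional; two-sided available by flag), BH
adjustment across sets, universe defaulting to the union of the supplied
collection (configurable).  No pathway content ships with the package.

No multiple-testing correction is applied to per-gene association by
default (raw p-values are reported); BH is available.

## Sample QC

Samples with fewer than 80,000 joint-called germline variants fail QC (a
count of exactly 80,000 passes).  A hypermutant exclusion exists as a
configurable somatic-count cutoff, off by default, because no principled
threshold presents itself.

## The synthetic cohort

`simulate_cohort(SimConfig)` emits every input table the pipeline consumes
plus a planted truth.  The defaults are the study conditions the package
targets: 571 cases against a 504-individual control population; a 260-gene
panel (139 TSG, 36 oncogene, 85 non-classified) laid out as non-overlapping
100-kb loci; one highlighted gene with case/control carrier rates 3.3% vs
0.79%; a background per-gene carrier rate of 0.0011 chosen so that roughly
a quarter of cases carry at least one pathogenic variant (1 − (1 −
0.0011)^260 ≈ 0.25); 16/143 of germline TSG carriers receive a somatic
second hit, split 2:14 between mutation and allele loss; and 68
somatic/somatic events (65 double mutations, 3 mutation + allele loss) are
planted across the cohort — so a default run plants on the order of 84
events.  Carrier draws are independent Bernoulli per (sample, gene).

Tumor VAFs for germline variants come from two Beta components: wild-type
lost, Beta(12, 5) (mean ≈ 0.71, ~4% of mass below 0.5 — those plantings
are exactly what the VAF filter must remove); wild-type retained,
Beta(30, 30) (tight around 0.5).  Ages are truncated normals on [20, 95]:
germline/somatic carriers (54.6, 11.2), somatic/somatic carriers
(60.6, 7.8), everyone else (58.8, 8.3).

Decoy material exercises every filter: germline variants with benign or
uncertain assertions, pathogenic-asserted variants with common allele
frequencies (1–10%), synonymous and benign-predicted missense somatic
mutations, and heterozygosity-retaining copy-number segments.  Every
(sample, gene) pair holding a planted hit is claimed so stray singleton
mutations and stray allele-loss segments can never combine into an
unplanned event — this is what makes noise-free recovery exactly scoreable
(sensitivity and precision 1.0 including subtype labels).  Noise switches
(assertion downgrades, predictor discordance, AF jitter) default to off.

All draws flow from one `numpy` generator seeded by a single integer; a
fixed seed reproduces every table byte for byte.  Variant positions and
alleles are synthetic placeholders inside panel intervals; no reference
genome, gene-length realism, hotspot structure, or read-level detail is
modeled.  Passing recovery tests therefore demonstrates the correctness of
the decision logic, not robustness to annotation noise, calling artifacts,
segmentation error, or tumor purity — real inputs must be quality-controlled
upstream.

## Numerical and calibration choices

* The per-seed mean of raw cross-product odds ratios is a poor calibration
  statistic at these carrier rates: it is upward-biased by ~25% (Jensen's
  inequality, plus occasional zero control cells making single draws
  infinite).  The simulator's calibration is therefore scored as the
  cross-product OR of the *seed-averaged* table — the ratio of mean odds —
  which converges to the configured odds ratio (≈ 4.29 at rates
  0.033/0.0079).
* Under the default age model at the observed group sizes (16 vs 67) the
  pooled t-test rejects at alpha = 0.05 in roughly two thirds of seeds; the
  acceptance script reports this power estimate rather than asserting a
  target, since a single study realization carries no power information.
* Exact-test ties are compared with relative tolerance 1e-7; the
  enumeration oracle in the test suite applies the same rule in integer
  arithmetic, so agreement is required to 1e-12.
* Degenerate inputs error early and loudly: all-zero tables, groups of
  size < 2, empty reference distributions, empty universes, carrier counts
  exceeding cohort sizes, invalid copy-number states (2·lcn > tcn).

## Problem sizes

The test suite simulates cohorts of 150–571 cases; the exhaustive exact-test
equivalence scan covers all 1.93 million 2x2 tables with total at most 80;
calibration and power use 2000 simulated seeds.  These sizes keep the full
suite and the acceptance script to a few minutes on one CPU while leaving
every check at full strength.

## Known limitations

* Pathogenicity assertions, predictor calls, and copy-number segments are
  trusted as annotated; the package contains no ACMG logic, no segmentation,
  and no re-genotyping.
* The burden test is a simple carrier-collapsing exact tail; no weights,
  covariates, or genotype-level aggregation.
* VAF validation uses the germline variant's tumor VAF only; depth-based
  checks are out of scope.
* The simulator's carrier model is independent per gene; linkage,
  population structure, and mutational signatures are not modeled.
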