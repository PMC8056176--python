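"""Exact case-control inference, carrier burden test, t comparison, ecdf.

The central object is the 2x2 carrier table

    ============  =========  =============
                  carriers   non-carriers
    cases         a          b
    controls      c          d
    ============  =========  =============

tested with Fisher's exact test.  The reported odds ratio is the
conditional maximum-likelihood estimate (the estimate exact-test software
reports): the value of the odds parameter psi under which the expected
count of the Fisher noncentral hypergeometric distribution, conditional on
the table margins, equals the observed ``a``.  Its exact 95% interval
solves the 0.025 tail-probability equations of that distribution, which is
why a zero control-carrier cell yields an infinite point estimate with a
finite lower bound.  The plain cross-product ratio ``ad/bc`` is reported
alongside.

The two-sided p-value follows the standard summation convention: the total
probability of all tables (under fixed margins) no more likely than the one
observed, with a relative tolerance of 1e-7 for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .hit_classification import Hit, HitType

#: relative tolerance when comparing hypergeometric probabilities for ties
#: (the convention used by mainstream exact-test implementations)
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class TwoByTwoResult:
    a: int
    b: int
    c: int
    d: int
    p_two_sided: float
    #: conditional-MLE odds ratio (may be inf when c == 0 or b == 0)
    or_point: float
    ci_low: float
    ci_high: float
    #: plain cross-product ratio a*d / (b*c); inf/nan when bc == 0
    or_sample: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError(f"p={self.p_two_sided} outside [0, 1]")
        # or_point is nan when a whole carrier (or non-carrier) margin is
        # empty: the odds parameter is then unidentifiable and the exact CI
        # degenerates to (0, inf)
        if not math.isnan(self.or_point) and \
                not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI does not bracket the point estimate")


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_two_sided: float
    #: mean(group A) - mean(group B)
    mean_diff: float
    ci_low: float
    ci_high: float
    df: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_diff <= self.ci_high):
            raise ValueError("CI does not bracket the mean difference")


# ---------------------------------------------------------------------------
# Fisher's exact test with conditional-MLE odds ratio
# ---------------------------------------------------------------------------

def hypergeom_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p for a 2x2 table by hypergeometric summation."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    N = a + b + c + d
    if N == 0:
        raise ValueError("all-zero table")
    K = a + c          # carriers
    n = a + b          # cases
    lo = max(0, n - (N - K))
    hi = min(n, K)
    xs = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(xs, N, K, n)
    observed = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= observed * (1.0 + TIE_RTOL)].sum()))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TwoByTwoResult:
    """Fisher's exact test with conditional-MLE OR and exact 95% CI.

    ``a``/``b`` are case carriers/non-carriers, ``c``/``d`` control
    carriers/non-carriers.  A zero carrier cell in controls gives an
    infinite point estimate with a finite exact lower bound.
    """
    p = hypergeom_two_sided_p(a, b, c, d)
    res = _scipy_odds_ratio([[a, b], [c, d]], kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    bc = b * c
    if bc > 0:
        or_sample = (a * d) / bc
    else:
        or_sample = float("inf") if a * d > 0 else float("nan")
    return TwoByTwoResult(a=a, b=b, c=c, d=d, p_two_sided=p,
                          or_point=float(res.statistic),
                          ci_low=float(ci.low), ci_high=float(ci.high),
                          or_sample=or_sample)


def carrier_burden_test(a: int, n_cases: int, c: int, n_controls: int) -> float:
    """One-sided (enrichment in cases) carrier-collapsing burden p-value.

    Collapses each gene to carrier / non-carrier per individual and tests
    the resulting 2x2 table with the exact one-sided hypergeometric tail
    P(X >= a) conditional on the margins.
    """
    if not (0 <= a <= n_cases) or not (0 <= c <= n_controls):
        raise ValueError("carrier counts exceed cohort sizes")
    N = n_cases + n_controls
    K = a + c
    return float(stats.hypergeom.sf(a - 1, N, K, n_cases))


# ---------------------------------------------------------------------------
# Two-sample t comparison
# ---------------------------------------------------------------------------

def student_t_two_sample(ages_a: Sequence[float], ages_b: Sequence[float],
                         pooled: bool = True) -> TTestResult:
    """Two-sided two-sample t-test on the mean difference (A - B).

    Pooled-variance Student's t by default; ``pooled=False`` selects the
    Welch variant.  Returns the t statistic, two-sided p, the mean
    difference, and its 95% confidence interval.
    """
    x = np.asarray(ages_a, dtype=float)
    y = np.asarray(ages_b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    mean_diff = float(x.mean() - y.mean())
    if pooled:
        df = len(x) + len(y) - 2
        sp2 = (((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
               / df)
        se = float(np.sqrt(sp2 * (1 / len(x) + 1 / len(y))))
    else:
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        se = float(np.sqrt(vx + vy))
        df = float((vx + vy) ** 2
                   / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1)))
    tcrit = float(stats.t.ppf(0.975, df)) if se > 0 else 0.0
    half = tcrit * se
    pval = float(res.pvalue)
    tstat = float(res.statistic)
    if se == 0.0 and mean_diff == 0.0:
        # identical constant groups: no variance, no evidence of difference
        tstat, pval = 0.0, 1.0
    return TTestResult(t_statistic=tstat, p_two_sided=pval,
                       mean_diff=mean_diff, ci_low=mean_diff - half,
                       ci_high=mean_diff + half, df=float(df))


# ---------------------------------------------------------------------------
# Empirical CDF percentile
# ---------------------------------------------------------------------------

def ecdf_percentile(values: Sequence[float], x: float) -> float:
    """Percentile of ``x`` against a reference distribution.

    100 * (number of reference values <= x) / n — the empirical CDF scaled
    to percent, as used for expression-rank statements.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("reference values must be non-empty")
    return float(100.0 * np.count_nonzero(arr <= x) / arr.size)


# ---------------------------------------------------------------------------
# Carrier tables from classified hits
# ---------------------------------------------------------------------------

def carrier_table_from_hits(hits: Iterable[Hit],
                            cohort_samples: Sequence[str],
                            gene: str) -> tuple[int, int]:
    """Case carrier / non-carrier counts for one gene.

    ``a`` = distinct samples with >= 1 germline pathogenic hit in ``gene``;
    ``b`` = cohort size - a.  Hits of other types are ignored; a hit sample
    missing from the cohort list is an error.
    """
    cohort = set(cohort_samples)
    if len(cohort) != len(cohort_samples):
        raise ValueError("duplicate sample ids in cohort list")
    carriers: set[str] = set()
    for h in hits:
        if h.hit_type is not HitType.GERMLINE_PATHOGENIC:
            continue
        if h.gene_symbol != gene:
            continue
        if h.sample_id not in cohort:
            raise ValueError(f"hit sample {h.sample_id!r} not in cohort list")
        carriers.add(h.sample_id)
    a = len(carriers)
    return a, len(cohort) - a


def associate_genes(hits: Sequence[Hit],
                    cohort_samples: Sequence[str],
                    control_counts: Mapping[str, tuple[int, int]],
                    ) -> list[dict]:
    """Per-gene case-control association against control carrier counts.

    ``control_counts`` maps gene -> (control carriers, control cohort size).
    Returns one row per gene with the 2x2 cells, exact two-sided p,
    conditional-MLE OR with CI, cross-product OR, and the one-sided carrier
    burden p.
    """
    n_cases = len(cohort_samples)
    rows: list[dict] = []
    for gene in sorted(control_counts):
        c, n_controls = control_counts[gene]
        a, b = carrier_table_from_hits(hits, cohort_samples, gene)
        res = fisher_exact_2x2(a, b, c, n_controls - c)
        rows.append({
            "gene": gene, "a": a, "b": b, "c": c, "d": n_controls - c,
            "case_rate": a / n_cases if n_cases else float("nan"),
            "control_rate": c / n_controls if n_controls else float("nan"),
            "p_two_sided": res.p_two_sided,
            "or_point": res.or_point,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "or_sample": res.or_sample,
            "p_burden": carrier_burden_test(a, n_cases, c, n_controls),
        })
    return rows


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (delegates to statsmodels)."""
    if len(pvalues) == 0:
        return []
    from statsmodels.stats.multitest import multipletests
    return list(multipletests(pvalues, method="fdr_bh")[1])
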