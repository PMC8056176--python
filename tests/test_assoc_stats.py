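"""Exact-test oracles, t-test closed forms, ecdf, and carrier tables.

The independent oracles here avoid the implementation's code paths:
two-sided p-values are re-derived by exact rational enumeration over all
tables with fixed margins, and the conditional-MLE odds ratio / CI are
checked against their defining equations evaluated with raw combinatorial
weights.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doublehit import (
    Hit,
    HitType,
    SimConfig,
    carrier_burden_test,
    carrier_table_from_hits,
    ecdf_percentile,
    fisher_exact_2x2,
    simulate_cohort,
    student_t_two_sample,
)
from doublehit.assoc_stats import bh_adjust, hypergeom_two_sided_p


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_two_sided_p(a, b, c, d):
    """Exact rational enumeration of all tables with the observed margins."""
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n - (N - K)), min(n, K)
    weights = {x: Fraction(math.comb(K, x) * math.comb(N - K, n - x),
                           math.comb(N, n)) for x in range(lo, hi + 1)}
    threshold = weights[a] * (Fraction(10**7 + 1, 10**7))   # same tie rule
    return float(min(Fraction(1), sum(w for w in weights.values()
                                      if w <= threshold)))


def oracle_one_sided_p(a, b, c, d):
    N, K, n = a + b + c + d, a + c, a + b
    hi = min(n, K)
    total = math.comb(N, n)
    return float(sum(Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
                     for x in range(a, hi + 1)))


def nchg_logweights(N, K, n, log_psi):
    lo, hi = max(0, n - (N - K)), min(n, K)
    xs = np.arange(lo, hi + 1)
    lw = (np.array([math.lgamma(K + 1) - math.lgamma(x + 1)
                    - math.lgamma(K - x + 1)
                    + math.lgamma(N - K + 1) - math.lgamma(n - x + 1)
                    - math.lgamma(N - K - n + x + 1) for x in xs])
          + xs * log_psi)
    lw -= lw.max()
    w = np.exp(lw)
    return xs, w / w.sum()


def nchg_mean(N, K, n, psi):
    xs, w = nchg_logweights(N, K, n, math.log(psi))
    return float((xs * w).sum())


def nchg_sf_geq(N, K, n, psi, a):
    xs, w = nchg_logweights(N, K, n, math.log(psi))
    return float(w[xs >= a].sum())


def nchg_cdf_leq(N, K, n, psi, a):
    xs, w = nchg_logweights(N, K, n, math.log(psi))
    return float(w[xs <= a].sum())


tables = st.tuples(st.integers(0, 20), st.integers(0, 20),
                   st.integers(0, 20), st.integers(0, 20)).filter(
    lambda t: sum(t) > 0 and (t[0] + t[1]) > 0 and (t[2] + t[3]) > 0)


# ---------------------------------------------------------------------------
# Two-sided p
# ---------------------------------------------------------------------------

def test_symmetric_table():
    res = fisher_exact_2x2(5, 5, 5, 5)
    assert res.p_two_sided == pytest.approx(1.0)
    assert res.or_point == pytest.approx(1.0, abs=1e-8)
    assert res.ci_low < 1.0 < res.ci_high


@settings(deadline=None, max_examples=150)
@given(t=tables)
def test_p_matches_exact_enumeration(t):
    a, b, c, d = t
    assert hypergeom_two_sided_p(a, b, c, d) == \
        pytest.approx(oracle_two_sided_p(a, b, c, d), abs=1e-12)


@settings(deadline=None, max_examples=100)
@given(t=tables)
def test_p_matches_scipy_fisher(t):
    from scipy.stats import fisher_exact
    a, b, c, d = t
    assert hypergeom_two_sided_p(a, b, c, d) == \
        pytest.approx(fisher_exact([[a, b], [c, d]]).pvalue, abs=1e-10)


@settings(deadline=None, max_examples=100)
@given(t=tables)
def test_transposing_groups_inverts_or(t):
    a, b, c, d = t
    res = fisher_exact_2x2(a, b, c, d)
    swapped = fisher_exact_2x2(c, d, a, b)
    assert swapped.p_two_sided == pytest.approx(res.p_two_sided, abs=1e-12)
    if res.or_point > 0 and math.isfinite(res.or_point):
        assert swapped.or_point == pytest.approx(1.0 / res.or_point, rel=1e-6)


def test_all_zero_table_rejected():
    with pytest.raises(ValueError):
        fisher_exact_2x2(0, 0, 0, 0)
    with pytest.raises(ValueError):
        fisher_exact_2x2(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# Conditional-MLE OR and exact CI
# ---------------------------------------------------------------------------

CMLE_TABLES = [(14, 410, 4, 500), (14, 410, 34, 10554), (6, 418, 1, 503),
               (6, 418, 41, 10547), (5, 419, 47, 10541), (3, 7, 2, 8),
               (10, 2, 3, 9), (1, 9, 2, 8)]


@pytest.mark.parametrize("t", CMLE_TABLES)
def test_cmle_defining_equation(t):
    """E[a | margins, psi_hat] = a under the noncentral hypergeometric law."""
    a, b, c, d = t
    res = fisher_exact_2x2(a, b, c, d)
    N, K, n = a + b + c + d, a + c, a + b
    assert abs(nchg_mean(N, K, n, res.or_point) - a) < 1e-8


@pytest.mark.parametrize("t", CMLE_TABLES)
def test_exact_ci_tail_probabilities(t):
    """CI endpoints solve the 0.025 tail equations of the conditional law."""
    a, b, c, d = t
    res = fisher_exact_2x2(a, b, c, d)
    N, K, n = a + b + c + d, a + c, a + b
    assert nchg_sf_geq(N, K, n, res.ci_low, a) == pytest.approx(0.025, abs=1e-6)
    if math.isfinite(res.ci_high):
        assert nchg_cdf_leq(N, K, n, res.ci_high, a) == \
            pytest.approx(0.025, abs=1e-6)


def test_zero_control_cell_gives_infinite_or():
    res = fisher_exact_2x2(5, 419, 0, 504)
    assert math.isinf(res.or_point)
    assert math.isinf(res.ci_high)
    assert math.isfinite(res.ci_low) and res.ci_low > 1.0


def test_or_sample_cross_product():
    res = fisher_exact_2x2(14, 410, 4, 500)
    assert res.or_sample == pytest.approx(7000 / 1640)
    # conditional-MLE shrinks toward 1 for enriched tables
    assert 1.0 < res.or_point < res.or_sample


@settings(deadline=None, max_examples=60)
@given(t=tables.filter(lambda t: min(t) >= 1 and t[0] * t[3] > t[1] * t[2]))
def test_cmle_at_most_cross_product_when_enriched(t):
    res = fisher_exact_2x2(*t)
    assert res.or_point <= res.or_sample * (1 + 1e-9)


# ---------------------------------------------------------------------------
# Burden test
# ---------------------------------------------------------------------------

def test_burden_no_carriers_anywhere():
    assert carrier_burden_test(0, 100, 0, 100) == pytest.approx(1.0)


@settings(deadline=None, max_examples=100)
@given(t=tables)
def test_burden_matches_one_sided_enumeration(t):
    a, b, c, d = t
    assert carrier_burden_test(a, a + b, c, c + d) == \
        pytest.approx(oracle_one_sided_p(a, b, c, d), abs=1e-12)


@settings(deadline=None, max_examples=60)
@given(t=tables.filter(
    lambda t: (t[0] / (t[0] + t[1])) > (t[2] / (t[2] + t[3]))))
def test_one_sided_not_above_two_sided_when_enriched(t):
    a, b, c, d = t
    assert carrier_burden_test(a, a + b, c, c + d) <= \
        hypergeom_two_sided_p(a, b, c, d) + 1e-12


def test_burden_rejects_impossible_counts():
    with pytest.raises(ValueError):
        carrier_burden_test(5, 4, 0, 100)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def test_t_identical_groups():
    res = student_t_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t_statistic == pytest.approx(0.0)
    assert res.p_two_sided == pytest.approx(1.0)
    assert res.mean_diff == pytest.approx(0.0)
    assert res.ci_low <= 0.0 <= res.ci_high


def test_t_textbook_pooled():
    """{1,2,3} vs {4,5,6}: closed-form pooled t re-derived in place."""
    from scipy import stats
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    # oracle by the textbook formula: s_p^2 = 1, se = sqrt(2/3)
    se = math.sqrt(2 / 3)
    t_expected = (2.0 - 5.0) / se
    p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
    half = stats.t.ppf(0.975, 4) * se
    res = student_t_two_sample(x, y)
    assert res.t_statistic == pytest.approx(t_expected, rel=1e-12)
    assert res.p_two_sided == pytest.approx(p_expected, rel=1e-12)
    assert res.mean_diff == pytest.approx(-3.0)
    assert res.ci_low == pytest.approx(-3.0 - half, rel=1e-12)
    assert res.ci_high == pytest.approx(-3.0 + half, rel=1e-12)
    assert res.df == 4


def test_t_welch_flag_changes_df():
    x = [1.0, 2.0, 3.0, 4.0]
    y = [10.0, 30.0, 50.0]
    pooled = student_t_two_sample(x, y, pooled=True)
    welch = student_t_two_sample(x, y, pooled=False)
    assert pooled.df == 5
    assert welch.df < 5
    assert pooled.p_two_sided != pytest.approx(welch.p_two_sided)


def test_t_small_group_rejected():
    with pytest.raises(ValueError):
        student_t_two_sample([1.0], [2.0, 3.0])


@settings(deadline=None, max_examples=50)
@given(x=st.lists(st.floats(-50, 50), min_size=2, max_size=10),
       y=st.lists(st.floats(-50, 50), min_size=2, max_size=10))
def test_t_ci_brackets_mean_diff(x, y):
    res = student_t_two_sample(x, y)
    assert res.ci_low <= res.mean_diff <= res.ci_high


# ---------------------------------------------------------------------------
# ecdf percentile
# ---------------------------------------------------------------------------

def test_ecdf_examples():
    values = list(range(1, 101))
    assert ecdf_percentile(values, 5) == pytest.approx(5.0)
    assert ecdf_percentile(values, 0.5) == 0.0
    assert ecdf_percentile(values, 1000) == 100.0
    with pytest.raises(ValueError):
        ecdf_percentile([], 1.0)


@settings(deadline=None, max_examples=100)
@given(values=st.lists(st.integers(-100, 100), min_size=1, max_size=50),
       x=st.integers(-120, 120))
def test_ecdf_counting_oracle(values, x):
    expected = 100.0 * sum(1 for v in values if v <= x) / len(values)
    assert ecdf_percentile(values, x) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Carrier tables
# ---------------------------------------------------------------------------

def _germ_hit(sample, gene="G1"):
    return Hit(sample, gene, HitType.GERMLINE_PATHOGENIC)


def test_carrier_table_distinct_samples():
    hits = [_germ_hit("S1"), _germ_hit("S1"), _germ_hit("S2", gene="OTHER")]
    a, b = carrier_table_from_hits(hits, ["S1", "S2", "S3"], "G1")
    assert (a, b) == (1, 2)


def test_carrier_table_empty():
    assert carrier_table_from_hits([], ["S1", "S2"], "G1") == (0, 2)


def test_carrier_table_unknown_sample_rejected():
    with pytest.raises(ValueError, match="not in cohort"):
        carrier_table_from_hits([_germ_hit("GHOST")], ["S1"], "G1")


def test_simulated_carrier_count_within_binomial_interval():
    """Planted carrier rate 3.3% at n=424: the recovered carrier count must
    sit inside the exact central 99% binomial band in every tested seed."""
    from scipy.stats import binom
    lo, hi = binom.ppf(0.005, 424, 0.033), binom.ppf(0.995, 424, 0.033)
    for seed in range(3):
        cfg = SimConfig(seed=seed, n_cases=424)
        cohort = simulate_cohort(cfg)
        carriers = {s for s, g, _ in cohort.truth.carriers if g == "TSG001"}
        assert lo <= len(carriers) <= hi


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_preserves_order_and_bounds():
    ps = [0.001, 0.02, 0.04, 0.2, 0.9]
    qs = bh_adjust(ps)
    assert all(q >= p for p, q in zip(ps, qs))
    assert all(q <= 1.0 for q in qs)
    assert qs == sorted(qs)
    assert bh_adjust([]) == []
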