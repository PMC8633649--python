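"""Exact conditional inference against brute-force enumeration oracles.

The oracles here are written independently of the implementation paths they
check: distributions by explicit enumeration of tables or subsets,
conditional MLEs by direct likelihood maximization (or scipy's noncentral
hypergeometric machinery), Fisher p-values by exact rational arithmetic.
"""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hst

from metapi.exact_inference import (
    CondDist,
    EstimateKind,
    Table2x2,
    cond_dist_2x2,
    cond_dist_continuous,
    conditional_mle,
    exact_ci,
    exact_logistic_2x2,
    exact_logistic_continuous,
    fisher_exact_p,
    fisher_exact_rxc,
)

# ---------------------------------------------------------------- oracles


def oracle_weights_2x2(r1, r2, c1):
    """Enumerate all 2x2 tables with the given margins; count per (1,1) cell."""
    out = {}
    for a in range(0, min(r1, c1) + 1):
        b, c = r1 - a, c1 - a
        d = r2 - c
        if b < 0 or c < 0 or d < 0:
            continue
        out[a] = math.comb(r1, a) * math.comb(r2, c)
    return out


def oracle_fisher_p(table: Table2x2) -> Fraction:
    """Two-sided Fisher p by exact rational arithmetic over the margin orbit."""
    r1, r2 = table.row_margins
    c1, _ = table.col_margins
    probs = {}
    for a, w in oracle_weights_2x2(r1, r2, c1).items():
        probs[a] = Fraction(w, math.comb(r1 + r2, c1))
    p_obs = probs[table.a]
    return sum(p for p in probs.values() if p <= p_obs * Fraction(10**7 + 1, 10**7))


def oracle_subset_weights(values, m):
    """Counts of subset sums of size m by explicit enumeration."""
    out = {}
    for comb in combinations(values, m):
        s = sum(comb)
        out[s] = out.get(s, 0) + 1
    return out


def oracle_cmle_loglik(dist: CondDist, t_obs: int) -> float:
    """Maximize the conditional log-likelihood directly on a beta grid."""
    lw = dist.log_weights
    tt = np.asarray(dist.support, dtype=float)

    def negll(beta):
        z = lw + tt * beta
        return -(t_obs * beta - (z.max() + np.log(np.exp(z - z.max()).sum())))

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(negll, bounds=(-30, 30), method="bounded",
                          options={"xatol": 1e-12})
    return math.exp(res.x)


# ------------------------------------------------------------ cond_dist_2x2


def test_cond_dist_2x2_unit_table():
    d = cond_dist_2x2(Table2x2(1, 1, 1, 1))
    assert d.support == (0, 1, 2)
    assert d.weights == (1, 4, 1)


def test_cond_dist_2x2_diagonal_symmetric():
    d = cond_dist_2x2(Table2x2(5, 0, 0, 5))
    assert d.support == tuple(range(6))
    assert d.weights == tuple(reversed(d.weights))


def test_cond_dist_2x2_empty_row_is_degenerate():
    d = cond_dist_2x2(Table2x2(0, 0, 3, 4))
    assert d.degenerate and len(d.support) == 1


@pytest.mark.parametrize("seed", range(5))
def test_cond_dist_2x2_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    a, b, c, d = rng.integers(0, 12, size=4)
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        a, b, c, d = a + 1, b + 1, c + 1, d + 1
    t = Table2x2(int(a), int(b), int(c), int(d))
    dist = cond_dist_2x2(t)
    r1, r2 = t.row_margins
    c1, _ = t.col_margins
    expect = oracle_weights_2x2(r1, r2, c1)
    assert dict(zip(dist.support, dist.weights)) == expect


# ------------------------------------------------------ cond_dist_continuous


def test_continuous_single_event_symmetric():
    d = cond_dist_continuous([1, 2, 3], [True, False, False])
    assert d.support == (1, 2, 3)
    assert d.weights == (1, 1, 1)


def test_continuous_tied_values():
    d = cond_dist_continuous([1, 1, 2], [True, False, False])
    assert d.support == (1, 2)
    assert d.weights == (2, 1)


def test_continuous_degenerate_outcomes_raise():
    with pytest.raises(ValueError, match="degenerate"):
        cond_dist_continuous([1, 2, 3], [True, True, True])


@pytest.mark.parametrize("seed", range(8))
def test_continuous_dp_matches_subset_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(4, 16))
    values = [int(v) for v in rng.integers(0, 10, size=n)]
    m = int(rng.integers(1, n))
    outcomes = [i < m for i in range(n)]
    d = cond_dist_continuous(values, outcomes)
    assert dict(zip(d.support, d.weights)) == oracle_subset_weights(values, m)


def test_continuous_shift_invariance_of_estimate():
    """Adding a constant to the covariate must not change the odds ratio."""
    rng = np.random.default_rng(3)
    xs = [int(v) for v in rng.integers(0, 10, size=12)]
    ys = [bool(v) for v in rng.integers(0, 2, size=12)]
    if not (0 < sum(ys) < len(ys)):
        ys[0], ys[1] = True, False
    f1 = exact_logistic_continuous(xs, ys)
    f2 = exact_logistic_continuous([x + 2000 for x in xs], ys)
    assert f1.or_estimate == pytest.approx(f2.or_estimate, rel=1e-8)
    assert f1.p_value == pytest.approx(f2.p_value, rel=1e-10)


# -------------------------------------------------------- CondDist algebra


@given(hst.integers(1, 8), hst.integers(1, 8), hst.integers(1, 8), hst.integers(1, 8))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_probabilities_sum_to_one_over_psi_grid(a, b, c, d):
    dist = cond_dist_2x2(Table2x2(a, b, c, d))
    for psi in (1e-4, 0.1, 1.0, 5.0, 1e3):
        assert dist.pmf(psi).sum() == pytest.approx(1.0, abs=1e-12)


@given(hst.integers(1, 10), hst.integers(1, 10), hst.integers(1, 10), hst.integers(1, 10))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_mean_strictly_increasing_in_psi(a, b, c, d):
    dist = cond_dist_2x2(Table2x2(a, b, c, d))
    grid = np.linspace(-6, 6, 25)
    means = [dist.mean(lp) for lp in grid]
    assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))


# ----------------------------------------------------------- Fisher exact


def test_fisher_prospero_table_matches_reference_corpus():
    """The PROSPERO 2x2 of the reference corpus gives p = 0.020."""
    dist = cond_dist_2x2(Table2x2(53, 6, 45, 17))
    p = fisher_exact_p(dist, 53)
    assert p == pytest.approx(0.0202, abs=5e-4)
    assert p == pytest.approx(st.fisher_exact([[53, 6], [45, 17]])[1], rel=1e-9)


def test_fisher_balanced_table_is_one():
    dist = cond_dist_2x2(Table2x2(5, 5, 5, 5))
    assert fisher_exact_p(dist, 5) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_fisher_matches_rational_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        a, b, c, d = a + 1, b + 1, c + 1, d + 1
    t = Table2x2(a, b, c, d)
    p = fisher_exact_p(cond_dist_2x2(t), t.a)
    assert p == pytest.approx(float(oracle_fisher_p(t)), abs=1e-12)


# -------------------------------------------------------- Freeman–Halton


def test_rxc_reduces_to_2x2():
    p_rxc = fisher_exact_rxc([[7, 3], [2, 9]])
    p_2x2 = fisher_exact_p(cond_dist_2x2(Table2x2(7, 3, 2, 9)), 7)
    assert p_rxc == pytest.approx(p_2x2, abs=1e-12)


def test_rxc_continent_table_is_highly_significant():
    assert fisher_exact_rxc([[30, 21], [17, 2], [52, 0]]) < 0.001


@pytest.mark.parametrize("seed", range(6))
def test_rxc_matches_full_enumeration(seed):
    """3x2 exact p equals a from-scratch enumeration for small n."""
    rng = np.random.default_rng(300 + seed)
    arr = rng.integers(0, 5, size=(3, 2))
    arr[0, 0] += 1
    arr[1, 1] += 1
    row_tot = arr.sum(axis=1)
    col1, n = int(arr[:, 0].sum()), int(arr.sum())

    def prob(x0, x1, x2):
        num = (math.comb(int(row_tot[0]), x0) * math.comb(int(row_tot[1]), x1)
               * math.comb(int(row_tot[2]), x2))
        return Fraction(num, math.comb(n, col1))

    p_obs = prob(*[int(v) for v in arr[:, 0]])
    total = Fraction(0)
    for x0 in range(int(row_tot[0]) + 1):
        for x1 in range(int(row_tot[1]) + 1):
            x2 = col1 - x0 - x1
            if 0 <= x2 <= int(row_tot[2]):
                p = prob(x0, x1, x2)
                if p <= p_obs * Fraction(10**7 + 1, 10**7):
                    total += p
    assert fisher_exact_rxc(arr) == pytest.approx(float(total), abs=1e-12)


def test_rxc_guard_rejects_huge_tables():
    with pytest.raises(ValueError, match="guard"):
        fisher_exact_rxc([[500, 500]] * 8)


# ------------------------------------------------- conditional MLE and CI


def test_cmle_symmetric_table_is_one():
    dist = cond_dist_2x2(Table2x2(5, 5, 5, 5))
    est, kind = conditional_mle(dist, 5)
    assert kind is EstimateKind.CONDITIONAL_MLE
    assert est == pytest.approx(1.0, abs=1e-9)


def test_cmle_attenuates_sample_odds_ratio():
    """Registration table: sample cross-product 3.34, conditional MLE 3.30."""
    fit = exact_logistic_2x2(Table2x2(53, 6, 45, 17))
    assert fit.estimate_kind is EstimateKind.CONDITIONAL_MLE
    assert fit.or_estimate == pytest.approx(3.3048, abs=2e-3)
    assert fit.or_estimate < (53 * 17) / (6 * 45)


def test_boundary_table_median_unbiased():
    """A zero cell puts T at the support edge: the MUE stays finite (~0.50)."""
    fit = exact_logistic_2x2(Table2x2(92, 23, 6, 0))
    assert fit.estimate_kind is EstimateKind.MEDIAN_UNBIASED
    assert fit.or_estimate == pytest.approx(0.5025, abs=2e-3)
    assert fit.ci_lower == 0.0
    assert fit.ci_upper == pytest.approx(3.6576, abs=2e-3)


@pytest.mark.parametrize(
    "table",
    [(53, 6, 45, 17), (30, 21, 17, 2), (39, 12, 59, 10), (8, 3, 4, 9), (2, 7, 6, 1)],
)
def test_cmle_matches_scipy_and_grid_oracle(table):
    t = Table2x2(*table)
    dist = cond_dist_2x2(t)
    est, kind = conditional_mle(dist, t.a)
    assert kind is EstimateKind.CONDITIONAL_MLE
    ref = st.contingency.odds_ratio(t.as_array(), kind="conditional").statistic
    assert est == pytest.approx(ref, rel=1e-8)
    assert est == pytest.approx(oracle_cmle_loglik(dist, t.a), rel=1e-6)


@given(hst.integers(1, 12), hst.integers(1, 12), hst.integers(1, 12), hst.integers(1, 12))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_cmle_row_swap_equivariance(a, b, c, d):
    t = Table2x2(a, b, c, d)
    dist = cond_dist_2x2(t)
    if dist.degenerate:
        return
    est, _ = conditional_mle(dist, t.a)
    ts = t.swap_rows()
    est_swap, _ = conditional_mle(cond_dist_2x2(ts), ts.a)
    assert est * est_swap == pytest.approx(1.0, rel=1e-7)


def test_exact_ci_registration_table():
    lo, hi = exact_ci(cond_dist_2x2(Table2x2(53, 6, 45, 17)), 53)
    assert lo == pytest.approx(1.1237, abs=2e-3)
    assert hi == pytest.approx(11.136, abs=2e-2)


def test_exact_ci_symmetric_about_one_on_log_scale():
    lo, hi = exact_ci(cond_dist_2x2(Table2x2(5, 5, 5, 5)), 5)
    assert math.log(lo) == pytest.approx(-math.log(hi), abs=1e-8)


def test_exact_ci_covers_estimate():
    for table in [(5, 3, 2, 8), (10, 1, 3, 6), (4, 4, 4, 4)]:
        fit = exact_logistic_2x2(Table2x2(*table))
        assert fit.ci_lower <= fit.or_estimate <= fit.ci_upper


def test_degenerate_support_raises():
    dist = cond_dist_2x2(Table2x2(0, 0, 3, 4))
    with pytest.raises(ValueError):
        conditional_mle(dist, dist.support[0])
    with pytest.raises(ValueError):
        exact_ci(dist, dist.support[0])


def test_continuous_cmle_matches_grid_oracle():
    rng = np.random.default_rng(17)
    xs = [int(v) for v in rng.integers(0, 8, size=14)]
    ys = [bool(v) for v in rng.integers(0, 2, size=14)]
    if not (0 < sum(ys) < len(ys)):
        ys[0], ys[1] = True, False
    dist = cond_dist_continuous(xs, ys)
    t_obs = sum(x for x, y in zip(xs, ys) if y)
    if dist.support[0] < t_obs < dist.support[-1]:
        est, _ = conditional_mle(dist, t_obs)
        assert est == pytest.approx(oracle_cmle_loglik(dist, t_obs), rel=1e-6)
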