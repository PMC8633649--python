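"""Exact conditional inference for binary-outcome association analyses.

This module implements the exact machinery behind the covariate analyses of
the reporting pipeline: Fisher's exact test for 2x2 and r x 2 contingency
tables, and exact (conditional) logistic regression for a single covariate —
binary, via the noncentral (extended) hypergeometric distribution of one cell
of a 2x2 table, or continuous, via the exact conditional distribution of the
sufficient statistic ``T = sum of covariate values over events`` given the
number of events.

Everything is built on :class:`CondDist`, the distribution of the sufficient
statistic over its attainable support.  Its base weights (the coefficients of
the conditional generating polynomial evaluated at odds ratio 1) are kept as
exact Python integers; probabilities at an arbitrary odds ratio ``psi`` are
formed in log space, so the module is deterministic and stable far into the
tails.

Conventions
-----------
For a 2x2 table ``[[a, b], [c, d]]`` (rows = covariate levels with the
reference level first, columns = outcome levels with the "event" second) the
sufficient statistic is the (1, 1) cell ``a`` and ``psi`` is the odds ratio
``(a*d)/(b*c)`` — equivalently the odds ratio of the event for the second row
level relative to the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "Table2x2",
    "CondDist",
    "ExactFit",
    "EstimateKind",
    "cond_dist_2x2",
    "cond_dist_continuous",
    "fisher_exact_p",
    "fisher_exact_rxc",
    "conditional_mle",
    "exact_ci",
    "exact_logistic_2x2",
    "exact_logistic_continuous",
]

#: relative tolerance used when deciding probability-mass ties in two-sided
#: exact tests; guards against sums flipping at machine precision.
TIE_TOL = 1e-7

#: guard on the number of candidate tables enumerated by the r x 2 test.
RXC_ENUM_GUARD = 10_000_000


class EstimateKind(str, Enum):
    CONDITIONAL_MLE = "conditional_mle"
    MEDIAN_UNBIASED = "median_unbiased"


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table of nonnegative integer counts.

    Rows index the covariate (reference level first), columns the outcome
    (event second).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swap_rows(self) -> "Table2x2":
        return Table2x2(self.c, self.d, self.a, self.b)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class CondDist:
    """Exact conditional distribution of a sufficient statistic.

    ``support`` lists the attainable values ``t`` in increasing order;
    ``weights`` holds the exact integer coefficients ``c_t`` of the
    generating polynomial, so that for any odds ratio ``psi > 0``

        P_psi(T = t) = c_t * psi**t / sum_s c_s * psi**s.

    ``degenerate`` flags a single-point support (no information about psi).
    """

    support: tuple[int, ...]
    weights: tuple[int, ...]
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        if len(self.support) != len(self.weights):
            raise ValueError("support and weights must have equal length")
        if len(self.support) == 0:
            raise ValueError("empty support")
        if any(w <= 0 for w in self.weights):
            raise ValueError("all base weights must be positive")
        if any(t2 <= t1 for t1, t2 in zip(self.support, self.support[1:])):
            raise ValueError("support must be strictly increasing")

    @property
    def log_weights(self) -> np.ndarray:
        # big ints can exceed float range; go through exact log
        return np.array([_log_int(w) for w in self.weights], dtype=float)

    def log_pmf(self, log_psi: float) -> np.ndarray:
        t = np.asarray(self.support, dtype=float)
        lw = self.log_weights + t * log_psi
        return lw - logsumexp(lw)

    def pmf(self, psi: float = 1.0) -> np.ndarray:
        """Probability mass over the support at odds ratio ``psi``."""
        if psi <= 0:
            raise ValueError("psi must be positive")
        return np.exp(self.log_pmf(math.log(psi)))

    def mean(self, log_psi: float) -> float:
        """E_psi[T], strictly increasing in log psi on a non-degenerate support."""
        p = np.exp(self.log_pmf(log_psi))
        return float(p @ np.asarray(self.support, dtype=float))

    def cdf(self, t: int, log_psi: float) -> float:
        """P_psi(T <= t)."""
        lp = self.log_pmf(log_psi)
        mask = np.asarray(self.support) <= t
        if not mask.any():
            return 0.0
        return float(np.exp(logsumexp(lp[mask])))

    def sf(self, t: int, log_psi: float) -> float:
        """P_psi(T >= t)."""
        lp = self.log_pmf(log_psi)
        mask = np.asarray(self.support) >= t
        if not mask.any():
            return 0.0
        return float(np.exp(logsumexp(lp[mask])))

    def index_of(self, t_obs: int) -> int:
        try:
            return self.support.index(t_obs)
        except ValueError:
            raise ValueError(f"t_obs={t_obs} not in support {self.support[:5]}...") from None


@dataclass(frozen=True)
class ExactFit:
    """Result of a single-covariate exact logistic analysis."""

    or_estimate: float
    estimate_kind: EstimateKind
    ci_lower: float
    ci_upper: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.or_estimate <= self.ci_upper):
            raise ValueError("estimate must lie inside its confidence interval")


def _log_int(x: int) -> float:
    """log of a (possibly huge) positive Python int."""
    if x <= 0:
        raise ValueError("log of nonpositive integer")
    try:
        return math.log(x)
    except OverflowError:
        m, e = math.frexp(float(x >> max(0, x.bit_length() - 53)))
        return math.log(m) + (e + max(0, x.bit_length() - 53)) * math.log(2.0)


def cond_dist_2x2(table: Table2x2) -> CondDist:
    """Conditional distribution of the (1,1) cell given all margins.

    The weights are the noncentral-hypergeometric coefficients
    ``C(r1, t) * C(r2, c1 - t)`` with ``r1, r2`` the row totals and ``c1``
    the first column total.
    """
    r1, r2 = table.row_margins
    c1, _ = table.col_margins
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = tuple(range(lo, hi + 1))
    weights = tuple(math.comb(r1, t) * math.comb(r2, c1 - t) for t in support)
    return CondDist(support, weights, degenerate=len(support) == 1)


def cond_dist_continuous(
    covariates: Sequence[float], outcomes: Sequence[bool]
) -> CondDist:
    """Conditional distribution of ``T = sum x_i over events`` given the event count.

    Conditioning on the number of events ``m``, the support is the set of
    attainable subset sums of size ``m`` over the covariate values, and the
    weight of each value is the number of size-``m`` subsets attaining it.
    Weights are computed by dynamic programming over the multiset of values
    (polynomial multiplication), never by explicit subset enumeration, and are
    exact integers throughout.

    Covariates must be integer-valued (e.g. calendar years); they are shifted
    by their minimum internally, which leaves the odds-ratio parameter
    untouched because the shift only relabels the support.
    """
    x = list(covariates)
    y = [bool(o) for o in outcomes]
    if len(x) != len(y):
        raise ValueError("covariates and outcomes must have equal length")
    if not x:
        raise ValueError("empty data")
    xi = []
    for v in x:
        iv = int(round(v))
        if abs(v - iv) > 1e-9:
            raise ValueError("covariates must be integer-valued for exact weights")
        xi.append(iv)
    m = sum(y)
    if m == 0 or m == len(y):
        raise ValueError("conditional distribution degenerate: all outcomes identical")

    shift = min(xi)
    vals = [v - shift for v in xi]
    # dp[j] maps attainable sum -> number of size-j subsets attaining it
    dp: list[dict[int, int]] = [dict() for _ in range(m + 1)]
    dp[0][0] = 1
    for v in vals:
        for j in range(m - 1, -1, -1):
            if not dp[j]:
                continue
            tgt = dp[j + 1]
            for s, cnt in dp[j].items():
                tgt[s + v] = tgt.get(s + v, 0) + cnt
    final = dp[m]
    support_shifted = sorted(final)
    # un-shift: T on the original covariate scale
    support = tuple(s + m * shift for s in support_shifted)
    weights = tuple(final[s] for s in support_shifted)
    return CondDist(support, weights, degenerate=len(support) == 1)


def fisher_exact_p(dist: CondDist, t_obs: int) -> float:
    """Two-sided Fisher exact p-value by probability-mass ordering.

    Sums, at ``psi = 1``, the probabilities of all support points whose mass
    does not exceed the observed mass (with a small relative tie tolerance).
    """
    i = dist.index_of(t_obs)
    p = dist.pmf(1.0)
    p_obs = p[i]
    return float(min(1.0, p[p <= p_obs * (1.0 + TIE_TOL)].sum()))


def _rxc_log_prob(rows: Sequence[int], col1: int, n: int) -> float:
    # log multivariate hypergeometric normalizer: log C(n, col1)
    return _log_int(math.comb(n, col1))


def fisher_exact_rxc(table: Sequence[Sequence[int]]) -> float:
    """Freeman–Halton exact test for an r x 2 table.

    Enumerates every table compatible with the observed margins, computes its
    multivariate hypergeometric probability, and sums the probabilities of
    tables no more probable than the observed one (same tie tolerance as the
    2x2 test).  Raises if the candidate-table count exceeds the enumeration
    guard.
    """
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    r = arr.shape[0]
    if r < 2:
        raise ValueError("need at least two rows")
    row_tot = arr.sum(axis=1)
    col1 = int(arr[:, 0].sum())
    n = int(arr.sum())
    if n == 0 or col1 == 0 or col1 == n:
        raise ValueError("degenerate margins")

    n_candidates = 1
    for rt in row_tot:
        n_candidates *= int(rt) + 1
        if n_candidates > RXC_ENUM_GUARD:
            raise ValueError(
                "candidate-table count exceeds enumeration guard; "
                "a Monte-Carlo approximation is required for tables this large"
            )

    log_norm = _log_int(math.comb(n, col1))
    log_comb_rows = [
        [_log_int(math.comb(int(rt), x)) if math.comb(int(rt), x) > 0 else -math.inf
         for x in range(int(rt) + 1)]
        for rt in row_tot
    ]

    def log_prob(xs: tuple[int, ...]) -> float:
        return sum(log_comb_rows[i][x] for i, x in enumerate(xs)) - log_norm

    obs = tuple(int(v) for v in arr[:, 0])
    lp_obs = log_prob(obs)
    thresh = lp_obs + math.log1p(TIE_TOL)

    # enumerate first-column counts per row summing to col1
    total = 0.0
    ranges = [range(int(rt) + 1) for rt in row_tot[:-1]]
    last_tot = int(row_tot[-1])
    for head in product(*ranges):
        rem = col1 - sum(head)
        if 0 <= rem <= last_tot:
            lp = log_prob(head + (rem,))
            if lp <= thresh:
                total += math.exp(lp)
    return float(min(1.0, total))


def _solve_log_psi(f, lo: float = -30.0, hi: float = 30.0) -> float:
    """Safeguarded root of a monotone function of log psi, expanding the bracket."""
    flo, fhi = f(lo), f(hi)
    tries = 0
    while flo * fhi > 0 and tries < 6:
        lo, hi = lo * 2, hi * 2
        flo, fhi = f(lo), f(hi)
        tries += 1
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise RuntimeError("failed to bracket root in log psi")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=300))


def conditional_mle(dist: CondDist, t_obs: int) -> tuple[float, EstimateKind]:
    """Odds-ratio point estimate from the conditional distribution.

    Interior ``t_obs``: the conditional MLE, i.e. the ``psi`` solving
    ``E_psi[T] = t_obs`` (the score equation of the conditional likelihood,
    strictly monotone in log psi).  Boundary ``t_obs``: the conditional MLE is
    0 or infinite, so the median-unbiased estimate is returned instead — the
    ``psi`` placing probability 0.5 on the observed tail.
    """
    if dist.degenerate:
        raise ValueError("estimate undefined: single-point support")
    dist.index_of(t_obs)
    t_min, t_max = dist.support[0], dist.support[-1]
    if t_min < t_obs < t_max:
        root = _solve_log_psi(lambda lp: dist.mean(lp) - t_obs)
        return math.exp(root), EstimateKind.CONDITIONAL_MLE
    if t_obs == t_min:
        root = _solve_log_psi(lambda lp: dist.cdf(t_obs, lp) - 0.5)
    else:
        root = _solve_log_psi(lambda lp: dist.sf(t_obs, lp) - 0.5)
    return math.exp(root), EstimateKind.MEDIAN_UNBIASED


def exact_ci(dist: CondDist, t_obs: int, level: float = 0.95) -> tuple[float, float]:
    """Exact tail-inversion confidence interval for the odds ratio.

    At ``alpha = 1 - level``: the lower bound solves
    ``P_psi(T >= t_obs) = alpha/2`` (0 when ``t_obs`` is the support minimum)
    and the upper bound solves ``P_psi(T <= t_obs) = alpha/2`` (infinite when
    ``t_obs`` is the support maximum).
    """
    if dist.degenerate:
        raise ValueError("confidence interval undefined: single-point support")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    dist.index_of(t_obs)
    alpha = 1.0 - level
    t_min, t_max = dist.support[0], dist.support[-1]
    if t_obs == t_min:
        lower = 0.0
    else:
        lower = math.exp(_solve_log_psi(lambda lp: dist.sf(t_obs, lp) - alpha / 2.0))
    if t_obs == t_max:
        upper = math.inf
    else:
        upper = math.exp(_solve_log_psi(lambda lp: dist.cdf(t_obs, lp) - alpha / 2.0))
    return lower, upper


def exact_logistic_2x2(table: Table2x2, level: float = 0.95) -> ExactFit:
    """Full exact analysis of a 2x2 table: estimate, exact CI, Fisher p."""
    dist = cond_dist_2x2(table)
    t_obs = table.a
    est, kind = conditional_mle(dist, t_obs)
    lo, hi = exact_ci(dist, t_obs, level)
    p = fisher_exact_p(dist, t_obs)
    return ExactFit(est, kind, lo, hi, p)


def exact_logistic_continuous(
    covariates: Sequence[float], outcomes: Sequence[bool], level: float = 0.95
) -> ExactFit:
    """Exact conditional logistic regression for one integer-valued covariate.

    Returns the odds ratio per unit of the covariate with its exact CI and the
    exact conditional (probability-ordering) p-value.
    """
    dist = cond_dist_continuous(covariates, outcomes)
    t_obs = int(sum(int(round(x)) for x, y in zip(covariates, outcomes) if y))
    est, kind = conditional_mle(dist, t_obs)
    lo, hi = exact_ci(dist, t_obs, level)
    p = fisher_exact_p(dist, t_obs)
    return ExactFit(est, kind, lo, hi, p)
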