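"""Spearman rank correlation with an exact small-sample permutation null.

For n untied observation pairs, Spearman's coefficient is

    r_s = 1 - 6 * sum(d_i^2) / (n^3 - n),

where d_i is the difference between the two ranks of item i.  Under the
null hypothesis of no association every pairing of rank vectors is equally
likely, so the distribution of r_s over all n! permutations gives exact
P-values and critical values.  At n = 10 the two-sided 0.01 critical value
is 0.794 — the screening threshold used throughout this package.

The exact null is tallied over the sum-of-squared-rank-differences
statistic by a dynamic programme over value subsets, which is equivalent
to (and is tested against) direct enumeration of all n! permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SpearmanResult",
    "NullDistribution",
    "CriticalValue",
    "CorrelationCall",
    "spearman_rs",
    "exact_null",
    "exact_pvalue",
    "critical_value",
    "monte_carlo_null",
    "permutation_with_sum_d2",
    "rank_pair_with_sum_d2",
    "correlation_call",
    "brute_force_null",
]

#: Snapping tolerance so floating-point representations of achievable r_s
#: values are counted inclusively in tail probabilities.
SNAP = 1e-9

#: Largest n for which the full n! permutation null is enumerated by default
#: (10! = 3,628,800); beyond this, use monte_carlo_null.
ENUMERATION_CEILING = 10


# ---------------------------------------------------------------------------
# The coefficient
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanResult:
    """Spearman's r_s for one pair of vectors.

    ``sum_d2`` is the integer sum of squared rank differences (only defined
    for untied data, where the classical formula applies exactly).
    """

    r_s: float
    tied: bool
    n: int
    sum_d2: Optional[int] = None


def spearman_rs(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation of two equal-length vectors.

    Untied data use the exact formula ``1 - 6*sum(d^2)/(n^3 - n)`` with
    integer arithmetic for ``sum(d^2)``; tied data fall back to the
    product-moment correlation of midranks and set the ``tied`` flag.

    Raises
    ------
    ValueError
        If lengths differ or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError(
            f"x and y must be 1-D and equal length, got {x.shape} and {y.shape}"
        )
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    tied = (np.unique(x).size < n) or (np.unique(y).size < n)
    if tied:
        r = float(np.corrcoef(rx, ry)[0, 1])
        return SpearmanResult(r_s=r, tied=True, n=n)
    d = rx.astype(np.int64) - ry.astype(np.int64)
    sum_d2 = int(np.dot(d, d))
    r = 1.0 - 6.0 * sum_d2 / (n ** 3 - n)
    return SpearmanResult(r_s=r, tied=False, n=n, sum_d2=sum_d2)


# ---------------------------------------------------------------------------
# The exact permutation null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullDistribution:
    """Distribution of r_s (equivalently of sum d^2) under random pairing.

    ``sum_d2`` holds the achievable sum-of-squared-rank-differences values
    (all even), ``counts`` the number of the ``total`` permutations
    realizing each.  ``exact`` is False for Monte-Carlo approximations.
    """

    n: int
    sum_d2: np.ndarray
    counts: np.ndarray
    total: int
    exact: bool = True

    @property
    def support(self) -> np.ndarray:
        """Achievable r_s values, descending (r_s = 1 at sum_d2 = 0)."""
        m = self.n ** 3 - self.n
        return 1.0 - 6.0 * self.sum_d2 / m

    def mean(self) -> float:
        return float(np.dot(self.support, self.counts) / self.total)

    def variance(self) -> float:
        s = self.support
        mu = self.mean()
        return float(np.dot((s - mu) ** 2, self.counts) / self.total)


def _sum_d2_tally(n: int) -> np.ndarray:
    """Counts of permutations of 1..n by sum((p_i - i)^2), index = value.

    Dynamic programme over subsets of assigned values: processing positions
    left to right, state = (set of values used, running sum of d^2).
    """
    max_s = n * (n * n - 1) // 3  # attained by the reversing permutation
    dp = np.zeros((1 << n, max_s + 1), dtype=np.int64)
    dp[0, 0] = 1
    order = sorted(range(1 << n), key=lambda m: bin(m).count("1"))
    for mask in order:
        row = dp[mask]
        if not row.any():
            continue
        pos = bin(mask).count("1") + 1  # next position to fill (1-based)
        for v in range(1, n + 1):
            bit = 1 << (v - 1)
            if mask & bit:
                continue
            d2 = (v - pos) ** 2
            if d2 == 0:
                dp[mask | bit] += row
            else:
                dp[mask | bit, d2:] += row[: max_s + 1 - d2]
    return dp[(1 << n) - 1]


@lru_cache(maxsize=None)
def exact_null(n: int) -> NullDistribution:
    """Exact permutation null of r_s for sample size ``n``.

    Valid for untied data.  Enumeration is capped at
    ``ENUMERATION_CEILING`` (n = 10, i.e. 3,628,800 permutations); larger
    n should use :func:`monte_carlo_null`.
    """
    if n < 3:
        raise ValueError(f"exact null requires n >= 3, got {n}")
    if n > ENUMERATION_CEILING:
        raise ValueError(
            f"n={n} exceeds the enumeration ceiling {ENUMERATION_CEILING}; "
            "use monte_carlo_null for an approximate null"
        )
    tally = _sum_d2_tally(n)
    sd2 = np.flatnonzero(tally)
    return NullDistribution(
        n=n,
        sum_d2=sd2.astype(np.int64),
        counts=tally[sd2],
        total=math.factorial(n),
        exact=True,
    )


def brute_force_null(n: int) -> NullDistribution:
    """Direct enumeration of all n! permutations (test oracle; n <= 8)."""
    if n > 8:
        raise ValueError("brute force is only intended for small n")
    base = np.arange(1, n + 1)
    counts: dict[int, int] = {}
    for p in permutations(base):
        s = int(sum((p[i] - base[i]) ** 2 for i in range(n)))
        counts[s] = counts.get(s, 0) + 1
    sd2 = np.array(sorted(counts), dtype=np.int64)
    return NullDistribution(
        n=n,
        sum_d2=sd2,
        counts=np.array([counts[s] for s in sd2], dtype=np.int64),
        total=math.factorial(n),
        exact=True,
    )


def monte_carlo_null(n: int, reps: int, seed: int) -> NullDistribution:
    """Approximate null from ``reps`` seeded random permutations.

    The returned distribution has ``exact=False``; its ``total`` is
    ``reps`` rather than n!.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    base = np.arange(1, n + 1, dtype=np.int64)
    perms = rng.permuted(np.tile(base, (reps, 1)), axis=1)
    sums = ((perms - base) ** 2).sum(axis=1)
    max_s = n * (n * n - 1) // 3
    tally = np.bincount(sums, minlength=max_s + 1)
    sd2 = np.flatnonzero(tally)
    return NullDistribution(
        n=n,
        sum_d2=sd2.astype(np.int64),
        counts=tally[sd2].astype(np.int64),
        total=reps,
        exact=False,
    )


def exact_pvalue(r_s: float, null: NullDistribution) -> float:
    """Two-sided tail probability P(|R| >= |r_s| - snap) under ``null``."""
    thresh = abs(r_s) - SNAP
    in_tail = np.abs(null.support) >= thresh
    return float(null.counts[in_tail].sum() / null.total)


@dataclass(frozen=True)
class CriticalValue:
    """Two-sided critical bounds of r_s at a given level, or their absence."""

    n: int
    alpha: float
    upper: Optional[float]
    lower: Optional[float]
    achieved_alpha: Optional[float]
    reason: Optional[str] = None

    @property
    def attainable(self) -> bool:
        return self.upper is not None


def critical_value(
    n: int, alpha: float, null: Optional[NullDistribution] = None
) -> CriticalValue:
    """Smallest achievable non-negative r_s whose two-sided exact tail
    probability is at most ``alpha``, with its negation.

    Returns an unattainable :class:`CriticalValue` (with an explanation)
    when even the extreme value |r_s| = 1 has tail probability above
    ``alpha`` — e.g. n = 3 at alpha = 0.01, where the minimum two-sided P
    is 2/6.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if null is None:
        null = exact_null(n)
    support = null.support
    nonneg = np.sort(support[support >= -SNAP])  # ascending
    for v in nonneg:
        p = exact_pvalue(v, null)
        if p <= alpha:
            v = float(max(v, 0.0))
            return CriticalValue(
                n=n, alpha=alpha, upper=v, lower=-v, achieved_alpha=p
            )
    return CriticalValue(
        n=n,
        alpha=alpha,
        upper=None,
        lower=None,
        achieved_alpha=None,
        reason=(
            f"no achievable value of |r_s| at n={n} has two-sided exact "
            f"P <= {alpha}; the minimum achievable P is "
            f"{exact_pvalue(1.0, null)}"
        ),
    )


# ---------------------------------------------------------------------------
# Per-gene correlation calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationCall:
    """Significance call for one gene against the propensity ranking."""

    gene_id: str
    r_s: float
    p_two_sided: float
    significant: bool
    direction: str  # "+" or "-"
    alpha: float
    tied: bool = False


def correlation_call(
    gene_id: str,
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.01,
    null: Optional[NullDistribution] = None,
) -> CorrelationCall:
    """Spearman call for one gene: exact P for untied data, a t
    approximation (flagged) when ties force midranks."""
    res = spearman_rs(x, y)
    if res.tied:
        p = _t_approx_pvalue(res.r_s, res.n)
    else:
        if null is None:
            null = exact_null(res.n)
        p = exact_pvalue(res.r_s, null)
    return CorrelationCall(
        gene_id=gene_id,
        r_s=res.r_s,
        p_two_sided=p,
        significant=bool(p <= alpha),
        direction="+" if res.r_s >= 0 else "-",
        alpha=alpha,
        tied=res.tied,
    )


def _t_approx_pvalue(r: float, n: int) -> float:
    """Large-sample t approximation for tied data (df = n - 2)."""
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


# ---------------------------------------------------------------------------
# Constructing rank pairs at a prescribed distance
# ---------------------------------------------------------------------------

def permutation_with_sum_d2(
    n: int, target: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """A permutation p of 1..n with sum((p_i - i)^2) equal to ``target``.

    Used to construct rank vectors realizing a prescribed r_s and to plant
    genes at a target rank correlation.  Randomized local search over
    transpositions starting from the identity; every even target in
    [0, n(n^2-1)/3] is achievable (odd targets are not: the statistic is
    always even).
    """
    max_s = n * (n * n - 1) // 3
    if target % 2 != 0 or not 0 <= target <= max_s:
        raise ValueError(
            f"target sum of squared rank differences must be even and in "
            f"[0, {max_s}], got {target}"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    idx = np.arange(1, n + 1, dtype=np.int64)
    for _ in range(100):  # random restarts; first almost always succeeds
        p = idx.copy()
        cur = 0
        ok = _local_search(p, idx, cur, target, rng)
        if ok is not None:
            return ok
        # restart from a random permutation
        p = rng.permutation(idx)
        cur = int(((p - idx) ** 2).sum())
        ok = _local_search(p, idx, cur, target, rng)
        if ok is not None:
            return ok
    raise RuntimeError(
        f"failed to construct a permutation with sum d^2 = {target} (n={n})"
    )


def _local_search(p, idx, cur, target, rng, max_iter=5000):
    n = p.size
    for _ in range(max_iter):
        if cur == target:
            return p
        best = None
        best_gap = abs(target - cur)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        rng.shuffle(pairs)
        for i, j in pairs:
            # delta of swapping positions i, j (0-based; ranks idx[i]=i+1)
            old = (p[i] - idx[i]) ** 2 + (p[j] - idx[j]) ** 2
            new = (p[j] - idx[i]) ** 2 + (p[i] - idx[j]) ** 2
            gap = abs(target - (cur + new - old))
            if gap < best_gap:
                best, best_gap = (i, j, int(new - old)), gap
                if gap == 0:
                    break
        if best is None:
            return None  # local optimum; caller restarts
        i, j, delta = best
        p[i], p[j] = p[j], p[i]
        cur += delta
    return None


def rank_pair_with_sum_d2(
    n: int, target: int, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two untied rank vectors of length n whose sum of squared rank
    differences equals ``target`` (first vector is 1..n)."""
    base = np.arange(1, n + 1, dtype=np.int64)
    return base, permutation_with_sum_d2(n, target, rng)
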