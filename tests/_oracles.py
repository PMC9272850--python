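"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the libraries)
they are used to check: rank-sum p-values by full enumeration of labelings,
binomial tails by exact rational summation, Fisher p by hypergeometric
enumeration, and percentiles by explicit sort-and-interpolate arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def ranksum_p_enumeration(x, y) -> float:
    """Two-sided rank-sum p by full enumeration over all C(n1+n2, n1)
    labelings of the pooled, tie-free data."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in x)
    mean = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    all_ranks = list(ranks.values())
    for combo in combinations(all_ranks, n1):
        total += 1
        if abs(sum(combo) - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def binom_sf_exact(x: int, n: int, p: float) -> float:
    """P(X >= x) for X ~ Binomial(n, p) by direct term-by-term summation.

    Small problems (n ≤ 200) are summed in exact rational arithmetic; larger
    ones in log space with compensated summation.
    """
    if x <= 0:
        return 1.0
    if x > n:
        return 0.0
    if n <= 200:
        pf = Fraction(p).limit_denominator(10 ** 15)
        q = 1 - pf
        total = sum(math.comb(n, j) * pf ** j * q ** (n - j)
                    for j in range(x, n + 1))
        return float(min(total, Fraction(1)))
    lp, lq = math.log(p), math.log1p(-p)
    lc = math.lgamma(n + 1)
    terms = [
        math.exp(lc - math.lgamma(j + 1) - math.lgamma(n - j + 1)
                 + j * lp + (n - j) * lq)
        for j in range(x, n + 1)
    ]
    return min(math.fsum(terms), 1.0)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration: the sum of the
    probabilities of all tables (with the observed margins) no more probable
    than the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k),
                        math.comb(n, c1))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        pk = pmf(k)
        if pk <= p_obs * (1 + Fraction(1, 10 ** 12)):
            total += pk
    return float(min(total, Fraction(1)))


def percentile_interpolated(values, prob: float) -> float:
    """Linear-interpolation percentile on the sorted values."""
    v = sorted(float(x) for x in values)
    if not v:
        raise ValueError("empty")
    h = (len(v) - 1) * prob / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return v[lo]
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def count_kmers_bruteforce(seqs: list[str], k: int) -> tuple[dict[str, int], int]:
    """Window-by-window k-mer counting; returns (counts, n_valid_windows)."""
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
            total += 1
    return counts, total


def pearson_bruteforce(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
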