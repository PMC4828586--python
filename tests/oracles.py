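"""Independent brute-force oracles used to certify the implementation.

Everything here is deliberately naive: exact rational hypergeometric
probabilities from binomial coefficients, convolution by enumerating the
Cartesian product of per-stratum supports, split-call merging as a
random-order pairwise closure, and the Mann-Whitney null by enumerating
every group assignment.  None of it shares code with the package.
"""

from __future__ import annotations

import itertools
import math
import random
from fractions import Fraction

from cnvburden.model import CnvCall


def hypergeom_pmf_exact(a: int, b: int, c: int, d: int) -> dict[int, Fraction]:
    """Exact rational pmf of the group-1 carrier count given the margins."""
    m, n1, n2 = a + c, a + b, c + d
    lo, hi = max(0, m - n2), min(m, n1)
    denom = math.comb(n1 + n2, m)
    return {
        s: Fraction(math.comb(n1, s) * math.comb(n2, m - s), denom)
        for s in range(lo, hi + 1)
    }


def convolve_enumerate(tables: list[tuple[int, int, int, int]]) -> dict[int, float]:
    """Null pmf of the summed count by full Cartesian-product enumeration."""
    pmfs = [hypergeom_pmf_exact(*t) for t in tables]
    out: dict[int, Fraction] = {}
    for combo in itertools.product(*(pmf.items() for pmf in pmfs)):
        s = sum(k for k, _ in combo)
        p = math.prod((v for _, v in combo), start=Fraction(1))
        out[s] = out.get(s, Fraction(0)) + p
    return {s: float(p) for s, p in out.items()}


def merge_closure(calls: list[CnvCall], policy, rng: random.Random) -> list[CnvCall]:
    """Pairwise merge closure: repeatedly pick any mergeable
    sorted-adjacent pair (in random order) until none remains."""
    from dataclasses import replace

    groups: dict[tuple, list[CnvCall]] = {}
    for c in calls:
        groups.setdefault((c.sample_id, c.chrom, c.copy_number), []).append(c)
    out = []
    for group in groups.values():
        group = sorted(group, key=lambda c: (c.start, c.end))
        while True:
            candidates = []
            for i in range(len(group) - 1):
                a, b = group[i], group[i + 1]
                gap = b.start - a.end - 1
                merged_len = max(a.end, b.end) - a.start + 1
                if gap < 0 or (
                    a.length_bp > policy.min_call_bp
                    and b.length_bp > policy.min_call_bp
                    and gap < policy.max_gap_fraction * merged_len
                ):
                    candidates.append(i)
            if not candidates:
                break
            i = rng.choice(candidates)
            a, b = group[i], group[i + 1]
            merged = replace(a, end=max(a.end, b.end), num_snps=a.num_snps + b.num_snps)
            group = group[:i] + [merged] + group[i + 2:]
        out.extend(group)
    return out


def mann_whitney_enumerate(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every assignment of
    the pooled (tie-free) values to the first group."""
    pooled = x + y
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi)

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    n = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / n
    p_ge = sum(1 for u in us if u >= u_obs) / n
    return min(1.0, 2 * min(p_le, p_ge))


def binom_upper_tail(x: int, n: int, f: float) -> float:
    """P(X >= x) for X ~ Binomial(n, f) by direct summation."""
    return sum(math.comb(n, k) * f**k * (1 - f) ** (n - k) for k in range(x, n + 1))
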