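"""Independent oracle implementations used to verify the package.

Everything here is deliberately naive and separate from the package code:
exact rational arithmetic, exhaustive enumeration, and one-line textbook
formulas. These are the reference values the pipeline is checked against.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def exact_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) as an exact rational."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(n, K) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(acc, total)


def enumeration_tail_counts(N: int, K: int, n: int) -> list[int]:
    """#{n-subsets of an N-universe with overlap >= k against a fixed
    K-prefix}, for k = 0..min(n, K), by brute-force enumeration."""
    kmax = min(n, K)
    hist = [0] * (kmax + 1)
    marked = set(range(K))
    for subset in combinations(range(N), n):
        hist[len(marked.intersection(subset))] += 1
    # cumulative upper tail
    tail = [0] * (kmax + 1)
    acc = 0
    for k in range(kmax, -1, -1):
        acc += hist[k]
        tail[k] = acc
    return tail


def bh_naive(pvals) -> list[float]:
    """Textbook Benjamini-Hochberg step-up in pure Python, in input order:
    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1 (suffix minimum carried
    from the largest rank down)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = float("inf")
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, pvals[i] * m / (rank_idx + 1))
        q[i] = min(1.0, running)
    return q


def partial_score_oracle(p_values, n_h: float) -> float:
    """One-line recomputation of the per-hallmark partial score."""
    if not p_values:
        return 0.0
    r = len(p_values)
    return sum(-math.log10(p) for p in p_values) * n_h * (1.0 + math.log2(r + 1) / 4.0)


def diversity_oracle(scores, n_t: int = 11) -> float:
    """One-line recomputation of the diversity factor (entropy in bits,
    normalized by log2(n_t))."""
    nz = [s for s in scores if s > 0]
    if not nz:
        return 0.0
    tot = sum(nz)
    h = -sum((s / tot) * math.log2(s / tot) for s in nz)
    return (len(nz) / n_t) * (1.0 + h / math.log2(n_t))


def total_oracle(combined, n_t: int = 11) -> float:
    return sum(combined) * diversity_oracle(combined, n_t)
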