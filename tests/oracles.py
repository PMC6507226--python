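"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: Fisher's two-sided p
by exhaustive enumeration of all tables sharing the observed margins, BH
by direct minimisation over the step-up definition, and the
hypergeometric upper tail by summing exact binomial-coefficient ratios.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric point probabilities no larger than the
    observed table's, enumerated over the margin-preserving tables."""
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    n = r1 + r2
    denom = comb(n, c1)
    kmin, kmax = max(0, c1 - r2), min(c1, r1)
    probs = [Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
             for k in range(kmin, kmax + 1)]
    obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    return float(sum(p for p in probs if p <= obs))


def bh_oracle(p) -> np.ndarray:
    """q_i = min over j with p_(j) >= p_i of p_(j) * m / rank(j),
    clipped at 1 — the step-up definition applied literally."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    sp = np.sort(p)
    ranks = np.arange(1, m + 1)
    vals = sp * m / ranks
    q = np.empty(m)
    for i in range(m):
        q[i] = min(1.0, vals[sp >= p[i]].min())
    return q


def hypergeom_upper_enum(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact summation."""
    denom = comb(N, n)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return float(total)


def window_tiling_enum(chrom_len: int, window: int, step: int) -> list[int]:
    """All full-window start positions by direct enumeration."""
    starts = []
    s = 1
    while s + window - 1 <= chrom_len:
        starts.append(s)
        s += step
    return starts or [1]
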