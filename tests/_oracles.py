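"""Independent brute-force oracles used to verify the statistics module.

These deliberately avoid the code paths of the implementation: Fisher
probabilities use exact rational arithmetic over binomial coefficients,
and the rank-sum U is computed from direct pairwise value comparisons
rather than ranks.
"""

import itertools
import math
from fractions import Fraction

import numpy as np

# Same documented tie-grouping tolerance as the implementation's
# two-sided rule, applied in exact arithmetic.
FISHER_TIE_TOL = Fraction(1, 10**7)


def fisher_two_sided_oracle(n_total: int, row1: int, col1: int) -> tuple[int, list[float]]:
    """Exact two-sided Fisher p for every observed top-left cell.

    Returns (kmin, [p for k in kmin..kmax]) computed with Fractions.
    """
    kmin = max(0, row1 + col1 - n_total)
    kmax = min(row1, col1)
    denom = math.comb(n_total, col1)
    pmf = [
        Fraction(math.comb(row1, k) * math.comb(n_total - row1, col1 - k), denom)
        for k in range(kmin, kmax + 1)
    ]
    out = []
    for p_obs in pmf:
        cut = p_obs * (1 + FISHER_TIE_TOL)
        out.append(float(min(sum(p for p in pmf if p <= cut), Fraction(1))))
    return kmin, out


def pairwise_u(a, b) -> float:
    """Mann-Whitney U of group a computed by direct value comparisons."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def rank_sum_two_sided_oracle(a, b) -> float:
    """Exact two-sided rank-sum p by exhaustive label enumeration."""
    a = list(a)
    b = list(b)
    pooled = a + b
    n1 = len(a)
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    u_obs = pairwise_u(a, b)
    dev = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in set(idx)]
        if abs(pairwise_u(ga, gb) - mu) >= dev - 1e-9:
            count += 1
        total += 1
    return count / total


def spearman_rho_formula(x, y) -> float:
    """Spearman rho via the d^2 formula (valid without ties)."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = float(((rx - ry) ** 2).sum())
    n = len(x)
    return 1 - 6 * d2 / (n * (n**2 - 1))


def binom_interval_99(n: int, p: float) -> tuple[int, int]:
    """Central 99% interval of Binomial(n, p) by pmf enumeration."""
    from math import comb

    pmf = [comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    cdf = np.cumsum(pmf)
    lo = int(np.searchsorted(cdf, 0.005))
    hi = int(np.searchsorted(cdf, 0.995))
    return lo, hi
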