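"""Shared exact and rank statistics used by every association stage.

All tests return a :class:`TestResult` carrying the statistic, the raw
p-value, an optional BH-adjusted p-value and a direction label, so that
downstream tables can be assembled uniformly.  Small-sample paths are
exact (full enumeration); large-sample paths use the standard normal or
t approximations with tie corrections.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "fisher_2x2",
    "bh_adjust",
    "rank_sum_test",
    "spearman_corr",
    "linear_fit",
]

# Relative tolerance used to group probability-mass ties in the two-sided
# Fisher rule.  Distinct hypergeometric pmf values for moderate table
# totals can differ by less than double rounding error, so a documented
# tolerance is part of the two-sided definition rather than a fudge.
FISHER_TIE_RTOL = 1e-7

# Cutovers between exact enumeration and asymptotic approximations.
RANK_SUM_EXACT_MAX_N = 12
SPEARMAN_EXACT_MAX_N = 7


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    test_name: str
    direction: str = "none"  # {"enriched", "depleted", "none"}
    p_adjusted: Optional[float] = None
    note: str = ""

    def __post_init__(self):
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")

    def with_adjusted(self, p_adj: float) -> "TestResult":
        return replace(self, p_adjusted=float(p_adj))


def _validate_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("negative cell count in 2x2 table")
    if not np.all(t == np.floor(t)):
        raise ValueError("non-integer cell count in 2x2 table")
    return t.astype(np.int64)


def fisher_2x2(table, sidedness: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    The two-sided p-value follows the probability-mass criterion: it sums
    the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table
    (up to :data:`FISHER_TIE_RTOL` relative tolerance).  One-sided tails
    are defined on the top-left cell: ``"greater"`` asks whether it is
    enriched, ``"less"`` whether it is depleted.

    Direction is labelled against the expectation under independence of
    the top-left cell (row1 * col1 / N).
    """
    t = _validate_2x2(table)
    a = int(t[0, 0])
    n_total = int(t.sum())
    row1 = int(t[0].sum())
    col1 = int(t[:, 0].sum())

    if n_total == 0:
        return TestResult(np.nan, 1.0, "fisher_exact", "none")

    hg = sps.hypergeom(n_total, row1, col1)
    kmin = max(0, row1 + col1 - n_total)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = hg.pmf(support)
    p_obs = pmf[a - kmin]

    if sidedness == "two-sided":
        p = float(pmf[pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)].sum())
    elif sidedness == "greater":
        p = float(hg.sf(a - 1))
    elif sidedness == "less":
        p = float(hg.cdf(a))
    else:
        raise ValueError(f"unknown sidedness: {sidedness!r}")
    p = min(p, 1.0)

    expected = row1 * col1 / n_total
    if a > expected:
        direction = "enriched"
    elif a < expected:
        direction = "depleted"
    else:
        direction = "none"

    odds = np.nan
    if t[0, 1] * t[1, 0] > 0:
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    elif t[0, 0] * t[1, 1] > 0:
        odds = np.inf
    return TestResult(float(odds), p, "fisher_exact", direction)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def _rank_sum_u(ranks_a: np.ndarray, n1: int) -> float:
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2.0)


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact by full enumeration of label assignments when the combined
    sample size is at most :data:`RANK_SUM_EXACT_MAX_N` (ties handled
    exactly through average ranks); otherwise the normal approximation
    with tie correction, without continuity correction.  The statistic is
    the U of ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = _rank_sum_u(ranks[:n1], n1)
    mu = n1 * n2 / 2.0

    if n <= RANK_SUM_EXACT_MAX_N:
        # Exact permutation distribution of U under random labelling.
        dev_obs = abs(u - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n1):
            u_perm = _rank_sum_u(ranks[list(idx)], n1)
            if abs(u_perm - mu) >= dev_obs - 1e-9:
                count += 1
            total += 1
        p = count / total
    else:
        tie_counts = np.unique(pooled, return_counts=True)[1]
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (u - mu) / math.sqrt(var)
            p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(p, 1.0)

    if u > mu:
        direction = "enriched"
    elif u < mu:
        direction = "depleted"
    else:
        direction = "none"
    return TestResult(u, p, "wilcoxon_rank_sum", direction)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    Exact permutation p-value for n <= :data:`SPEARMAN_EXACT_MAX_N`,
    t-distribution approximation otherwise.  Constant inputs give an
    undefined rho (NaN) with p = 1, flagged in ``note``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    rho = _spearman_rho(rx, ry)
    if math.isnan(rho):
        return TestResult(float("nan"), 1.0, "spearman", "none", note="constant input")

    if n <= SPEARMAN_EXACT_MAX_N:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _spearman_rho(rx, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        # Two-sided p from the t approximation.
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = float(2.0 * sps.t.sf(abs(tstat), df=n - 2))
    direction = "enriched" if rho > 0 else ("depleted" if rho < 0 else "none")
    return TestResult(rho, min(p, 1.0), "spearman", direction)


def linear_fit(
    response: Sequence[float],
    predictor: Sequence[float],
    covariate_labels: Optional[Sequence] = None,
) -> tuple[float, TestResult]:
    """OLS slope of ``response`` on ``predictor`` with categorical covariates.

    ``covariate_labels`` (e.g. cancer-type labels) are encoded as
    indicator columns (first level as reference).  Returns the slope and
    a two-sided t-test on it.  A constant response is returned as slope 0
    with p = 1 and a note, because the slope variance is undefined.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.size != x.size:
        raise ValueError("response and predictor must have equal length")

    cols = [np.ones(y.size), x]
    names = ["const", "predictor"]
    if covariate_labels is not None:
        labels = np.asarray(covariate_labels)
        if labels.size != y.size:
            raise ValueError("covariate_labels length mismatch")
        levels = sorted(set(labels.tolist()))
        for lev in levels[1:]:
            cols.append((labels == lev).astype(float))
            names.append(f"type[{lev}]")
    design = np.column_stack(cols)

    if y.size <= design.shape[1]:
        raise ValueError("need more observations than fitted coefficients")
    if np.ptp(y) == 0:
        return 0.0, TestResult(0.0, 1.0, "ols_slope_t", "none", note="constant response")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("collinear predictor/covariates")

    model = sm.OLS(y, design).fit()
    beta = float(model.params[1])
    p = float(model.pvalues[1])
    if math.isnan(p):
        p = 1.0
    direction = "enriched" if beta > 0 else ("depleted" if beta < 0 else "none")
    return beta, TestResult(beta, min(p, 1.0), "ols_slope_t", direction)
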