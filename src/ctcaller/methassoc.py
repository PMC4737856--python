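"""Promoter-methylation association with EECTP activation.

Works on a promoter-level beta matrix (one row per gene, one column per
sample, values in [0, 1]).  Cohort level: OLS of activated-EECTP counts
on the per-sample mean promoter beta over EECTPs, optionally adding the
genome-wide mean beta as a covariate to separate gene-set-specific
demethylation from global hypomethylation.  Gene level: Wilcoxon
rank-sum of betas between EE and non-EE samples, BH-adjusted.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .mutassoc import AssociationResult

__all__ = [
    "mean_promoter_beta",
    "methylation_vs_activation",
    "per_gene_methylation_test",
    "per_gene_methylation_tests",
]


def _validate_betas(matrix: pd.DataFrame) -> None:
    vals = matrix.to_numpy(dtype=float)
    bad = vals[~np.isnan(vals)]
    if bad.size and (bad.min() < 0 or bad.max() > 1):
        raise ValueError("beta values must lie in [0, 1]")


def mean_promoter_beta(
    matrix: pd.DataFrame, genes: Sequence[str]
) -> tuple[pd.Series, pd.Series]:
    """Per-sample mean beta over a gene subset, ignoring missing values.

    Returns (means, per-sample missing counts); a sample with no
    observed beta in the subset gets a NaN mean.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene subset must be non-empty")
    missing_genes = set(genes) - set(matrix.index)
    if missing_genes:
        raise ValueError(f"genes absent from methylation matrix: {sorted(missing_genes)}")
    sub = matrix.loc[genes]
    _validate_betas(sub)
    means = sub.mean(axis=0, skipna=True)
    n_missing = sub.isna().sum(axis=0)
    means.name = "mean_beta"
    n_missing.name = "n_missing"
    return means, n_missing


def methylation_vs_activation(
    mean_beta: pd.Series,
    activated: pd.Series,
    cancer_types: Optional[pd.Series] = None,
    genomewide_mean: Optional[pd.Series] = None,
) -> AssociationResult:
    """OLS of activated counts on mean EECTP promoter beta.

    Missing values are dropped listwise.  When ``genomewide_mean`` is
    supplied it enters as an additional continuous covariate by
    residualising both response and predictor on it together with the
    cancer-type indicators (equivalent to including it in the design).
    """
    df = pd.DataFrame({"beta": mean_beta, "activated": activated})
    if cancer_types is not None:
        df["type"] = cancer_types
    if genomewide_mean is not None:
        df["gw"] = genomewide_mean
    df = df.dropna()

    import statsmodels.api as sm

    cols = [np.ones(len(df)), df["beta"].to_numpy()]
    if cancer_types is not None:
        labels = df["type"].to_numpy()
        for lev in sorted(set(labels.tolist()))[1:]:
            cols.append((labels == lev).astype(float))
    if genomewide_mean is not None:
        cols.append(df["gw"].to_numpy())
    design = np.column_stack(cols)
    y = df["activated"].to_numpy(dtype=float)
    if len(df) <= design.shape[1]:
        raise ValueError("too few complete samples for the regression")
    if np.ptp(y) == 0:
        return AssociationResult(
            "cohort", 0.0,
            stats.TestResult(0.0, 1.0, "ols_slope_t", "none", note="constant response"),
            len(df),
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("collinear design")
    fit = sm.OLS(y, design).fit()
    beta = float(fit.params[1])
    p = min(float(fit.pvalues[1]), 1.0)
    direction = "enriched" if beta > 0 else ("depleted" if beta < 0 else "none")
    return AssociationResult(
        "cohort", beta, stats.TestResult(beta, p, "ols_slope_t", direction), len(df)
    )


def per_gene_methylation_test(
    betas: pd.Series, ee_flags: pd.Series
) -> Optional[stats.TestResult]:
    """Rank-sum of promoter betas in EE vs non-EE samples for one gene.

    Returns None (not testable) when either stratum is empty after
    dropping missing betas.
    """
    df = pd.DataFrame({"beta": betas, "ee": ee_flags}).dropna(subset=["beta"])
    g_ee = df.loc[df["ee"].astype(bool), "beta"].to_numpy()
    g_no = df.loc[~df["ee"].astype(bool), "beta"].to_numpy()
    if g_ee.size == 0 or g_no.size == 0:
        return None
    return stats.rank_sum_test(g_ee, g_no)


def per_gene_methylation_tests(
    matrix: pd.DataFrame, ee_flags: pd.DataFrame, genes: Sequence[str]
) -> pd.DataFrame:
    """Per-gene EE vs non-EE beta comparison with BH adjustment.

    Genes absent from the methylation matrix (e.g. chromosome-Y genes on
    arrays without Y probes) are reported as not testable rather than
    dropped silently.
    """
    rows = []
    for g in genes:
        if g not in matrix.index or g not in ee_flags.index:
            rows.append({"gene_id": g, "testable": False, "statistic": np.nan,
                         "p_value": np.nan, "direction": "none",
                         "reason": "absent_from_matrix"})
            continue
        samples = [s for s in matrix.columns if s in ee_flags.columns]
        t = per_gene_methylation_test(matrix.loc[g, samples], ee_flags.loc[g, samples])
        if t is None:
            rows.append({"gene_id": g, "testable": False, "statistic": np.nan,
                         "p_value": np.nan, "direction": "none",
                         "reason": "empty_stratum"})
        else:
            rows.append({"gene_id": g, "testable": True, "statistic": t.statistic,
                         "p_value": t.p_value, "direction": t.direction, "reason": ""})
    out = pd.DataFrame(rows).set_index("gene_id")
    ok = out["testable"]
    out["p_adjusted"] = np.nan
    if ok.any():
        out.loc[ok, "p_adjusted"] = stats.bh_adjust(out.loc[ok, "p_value"])
    return out
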