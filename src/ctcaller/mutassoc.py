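"""Association between EECTP activation and somatic mutation burden.

The per-sample SMG mutation ratio is the share of a sample's somatic
mutations that fall in significantly mutated genes (SMGs); genes can be
excluded from both numerator and denominator (the typical exclusion is
TP53, whose mutations track genome instability rather than pathway
drive).  The ratio is undefined (and the sample dropped) when a sample
has no mutations left after exclusion.

Cohort level: OLS of the per-sample activated-EECTP count on the
mutation ratio, adjusting for cancer type.  Gene level: per SMG a
Wilcoxon rank-sum of activated counts in mutated vs non-mutated
samples, and per (SMG, EECTP) pair a two-sided Fisher exact test of the
mutation x EE 2x2 with the direction labelled against expected
co-occurrence under independence; BH adjustment within each family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "AssociationResult",
    "mutation_ratio",
    "mutation_ratios",
    "mutation_status",
    "ratio_vs_activation",
    "gene_level_tests",
]


@dataclass(frozen=True)
class AssociationResult:
    unit: str
    effect: float
    test: stats.TestResult
    n_used: int


def mutation_ratio(
    sample_mutations: Sequence[str],
    smg_list: set,
    exclude: set = frozenset(),
) -> Optional[float]:
    """Share of a sample's mutations hitting SMGs, after exclusions.

    ``sample_mutations`` is the list of mutated gene symbols for one
    sample, one entry per mutation (multiplicities count).  Returns None
    when no mutations remain in the denominator.
    """
    smg_list = set(smg_list)
    if not smg_list:
        raise ValueError("smg_list must be non-empty")
    exclude = set(exclude)
    kept = [g for g in sample_mutations if g not in exclude]
    if not kept:
        return None
    numer = sum(1 for g in kept if g in smg_list)
    return numer / len(kept)


# "total mutation number" counts every MAF row by default; silent
# variants can be excluded via nonsilent_only
SILENT_CLASSES = frozenset({"Silent"})


def _maybe_nonsilent(maf: pd.DataFrame, nonsilent_only: bool) -> pd.DataFrame:
    if not nonsilent_only:
        return maf
    return maf[~maf["Variant_Classification"].isin(SILENT_CLASSES)]


def mutation_ratios(
    maf: pd.DataFrame,
    samples: Sequence[str],
    smg_list: set,
    exclude: set = frozenset(),
    nonsilent_only: bool = False,
) -> pd.Series:
    """Per-sample mutation ratio from a MAF-like table.

    Requires columns Hugo_Symbol and Tumor_Sample_Barcode.  Samples with
    an undefined ratio get NaN.
    """
    maf = _maybe_nonsilent(maf, nonsilent_only)
    by_sample = maf.groupby("Tumor_Sample_Barcode")["Hugo_Symbol"].apply(list)
    out = {}
    for s in samples:
        muts = by_sample.get(s, [])
        r = mutation_ratio(muts, smg_list, exclude)
        out[s] = np.nan if r is None else r
    return pd.Series(out, name="mutation_ratio").reindex(samples)


def mutation_status(
    maf: pd.DataFrame,
    samples: Sequence[str],
    genes: Sequence[str],
    nonsilent_only: bool = False,
) -> pd.DataFrame:
    """Boolean genes x samples mutation-status matrix from a MAF-like table."""
    maf = _maybe_nonsilent(maf, nonsilent_only)
    status = pd.DataFrame(False, index=list(genes), columns=list(samples))
    sel = maf[maf["Hugo_Symbol"].isin(set(genes)) &
              maf["Tumor_Sample_Barcode"].isin(set(samples))]
    for row in sel.itertuples():
        status.loc[row.Hugo_Symbol, row.Tumor_Sample_Barcode] = True
    return status


def ratio_vs_activation(
    ratios: pd.Series,
    activated: pd.Series,
    cancer_types: Optional[pd.Series] = None,
) -> AssociationResult:
    """OLS of activated-EECTP counts on mutation ratios (cancer-type adjusted).

    Samples with a missing ratio are dropped listwise.
    """
    df = pd.DataFrame({"ratio": ratios, "activated": activated})
    labels = None
    if cancer_types is not None:
        df["type"] = cancer_types
    df = df.dropna()
    if cancer_types is not None:
        labels = df["type"].to_numpy()
    beta, test = stats.linear_fit(
        df["activated"].to_numpy(), df["ratio"].to_numpy(), labels
    )
    return AssociationResult("cohort", beta, test, len(df))


def gene_level_tests(
    mut_status: pd.DataFrame,
    ee_flags: pd.DataFrame,
    activated: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SMG and per-(SMG, EECTP) association tests.

    ``mut_status``: SMGs x samples booleans; ``ee_flags``: EECTPs x
    samples booleans; ``activated``: per-sample activated counts.  Both
    result tables carry BH-adjusted p-values within their own family.
    Strata that cannot be tested (an SMG mutated in none or all samples)
    are marked ``testable = False`` with p = NaN.
    """
    samples = [s for s in mut_status.columns if s in ee_flags.columns]
    mut = mut_status[samples].astype(bool)
    ee = ee_flags[samples].astype(bool)
    act = activated.reindex(samples)

    smg_rows = []
    for g in mut.index:
        m = mut.loc[g].to_numpy()
        if 0 < m.sum() < len(m):
            t = stats.rank_sum_test(act[m].to_numpy(), act[~m].to_numpy())
            smg_rows.append(
                {"smg": g, "testable": True, "statistic": t.statistic,
                 "p_value": t.p_value, "direction": t.direction,
                 "n_mutated": int(m.sum())}
            )
        else:
            smg_rows.append(
                {"smg": g, "testable": False, "statistic": np.nan,
                 "p_value": np.nan, "direction": "none",
                 "n_mutated": int(m.sum())}
            )
    smg_df = pd.DataFrame(smg_rows).set_index("smg")
    ok = smg_df["testable"]
    smg_df["p_adjusted"] = np.nan
    if ok.any():
        smg_df.loc[ok, "p_adjusted"] = stats.bh_adjust(smg_df.loc[ok, "p_value"])

    pair_rows = []
    n = len(samples)
    for g in mut.index:
        m = mut.loc[g].to_numpy()
        for e_gene in ee.index:
            e = ee.loc[e_gene].to_numpy()
            both = int((m & e).sum())
            table = [
                [both, int((m & ~e).sum())],
                [int((~m & e).sum()), int((~m & ~e).sum())],
            ]
            expected = m.sum() * e.sum() / n if n else 0.0
            t = stats.fisher_2x2(table)
            direction = (
                "depleted" if both < expected
                else ("enriched" if both > expected else "none")
            )
            pair_rows.append(
                {"smg": g, "eectp": e_gene, "n_both": both,
                 "expected_both": expected, "p_value": t.p_value,
                 "direction": direction}
            )
    pair_df = pd.DataFrame(pair_rows)
    if len(pair_df):
        pair_df["p_adjusted"] = stats.bh_adjust(pair_df["p_value"])
    return smg_df, pair_df
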