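"""Per-cohort calling of expression, extreme expression (EE) and
cancer-testis (CT) status.

A gene is *expressed* in a tumour sample when its normalized read count
strictly exceeds the expression threshold (default 5).  A sample shows
*extreme expression* of a gene when the count strictly exceeds
``max(floor, Q3 + k * IQR)`` computed over the whole cohort vector
(defaults floor = 32, k = 3); the floor keeps the rule meaningful for
genes the cohort mostly does not express, where Q3 and IQR collapse
to 0, while the quartile term makes it scale-robust when a baseline
exists.  Quartiles use linear interpolation (type-7).

Status chain per gene and cancer type:

* CT gene:   high-confidence testis-specific (category C1) and expressed
             in at least 1% of samples;
* EECTG:     CT gene with EE in at least 1% of samples;
* EECTP:     EECTG whose protein is a testis-specific protein (TSP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEParams",
    "CTCallResult",
    "expression_fractions",
    "call_ee",
    "call_ct_status",
    "activated_counts",
    "call_cohort",
]

EXPRESSION_THRESHOLD = 5.0
FRACTION_THRESHOLD = 0.01


@dataclass(frozen=True)
class EEParams:
    floor: float = 32.0
    k: float = 3.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be non-negative")


@dataclass(frozen=True)
class CTCallResult:
    gene_id: str
    cancer_type: str
    expressed_fraction: float
    ee_fraction: float
    ee_flags: np.ndarray
    is_ct: bool
    is_eectg: bool
    is_eectp: bool

    def __post_init__(self):
        if self.ee_fraction > self.expressed_fraction + 1e-12:
            raise ValueError("ee_fraction exceeds expressed_fraction")
        if self.is_eectp and not self.is_eectg:
            raise ValueError("EECTP implies EECTG")
        if self.is_eectg and not self.is_ct:
            raise ValueError("EECTG implies CT")


def _validate_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty count vector")
    if np.any(x < 0):
        raise ValueError("negative count")
    return x


def expression_fractions(
    counts: Sequence[float], expression_threshold: float = EXPRESSION_THRESHOLD
) -> tuple[float, np.ndarray]:
    """Fraction and per-sample flags of samples with count > threshold."""
    x = _validate_counts(counts)
    flags = x > expression_threshold
    return float(flags.mean()), flags


def ee_threshold(counts: Sequence[float], params: EEParams = EEParams()) -> float:
    x = _validate_counts(counts)
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation (type-7)
    return max(params.floor, q3 + params.k * (q3 - q1))


def call_ee(counts: Sequence[float], params: EEParams = EEParams()) -> np.ndarray:
    """Per-sample EE flags: count > max(floor, Q3 + k*IQR), strict."""
    x = _validate_counts(counts)
    return x > ee_threshold(x, params)


def call_ct_status(
    gene_id: str,
    cancer_type: str,
    category: str,
    protein_class: str,
    counts: Sequence[float],
    expression_threshold: float = EXPRESSION_THRESHOLD,
    ee_params: EEParams = EEParams(),
    fraction_threshold: float = FRACTION_THRESHOLD,
    ct_categories: frozenset = frozenset({"C1"}),
) -> CTCallResult:
    """Call CT / EECTG / EECTP status for one gene in one cohort."""
    expressed_fraction, _ = expression_fractions(counts, expression_threshold)
    flags = call_ee(counts, ee_params)
    ee_fraction = float(flags.mean())
    is_ct = category in ct_categories and expressed_fraction >= fraction_threshold
    is_eectg = is_ct and ee_fraction >= fraction_threshold
    is_eectp = is_eectg and protein_class == "TSP"
    return CTCallResult(
        gene_id, cancer_type, expressed_fraction, ee_fraction, flags,
        is_ct, is_eectg, is_eectp,
    )


def activated_counts(ee_flags: pd.DataFrame, eectp_genes: Sequence[str]) -> pd.Series:
    """Per-sample number of EECTPs flagged EE (genes x samples boolean input)."""
    eectp_genes = [g for g in eectp_genes]
    missing = set(eectp_genes) - set(ee_flags.index)
    if missing:
        raise ValueError(f"EE flags missing for EECTPs: {sorted(missing)}")
    if not eectp_genes:
        return pd.Series(0, index=ee_flags.columns, name="activated_eectps")
    counts = ee_flags.loc[eectp_genes].sum(axis=0).astype(int)
    counts.name = "activated_eectps"
    return counts


def call_cohort(
    cohort: pd.DataFrame,
    classification: pd.DataFrame,
    cancer_type: str,
    protein_classes: Optional[pd.Series] = None,
    expression_threshold: float = EXPRESSION_THRESHOLD,
    ee_params: EEParams = EEParams(),
    fraction_threshold: float = FRACTION_THRESHOLD,
    ct_categories: frozenset = frozenset({"C1"}),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call CT status for every gene of a cohort matrix (genes x samples).

    ``classification`` is the table from ``specificity.classify_genes``
    (indexed by gene id, with a ``category`` column); ``protein_classes``
    maps gene id to its protein class, defaulting to ``no_data``.
    Returns (calls table, genes x samples EE-flag matrix).
    """
    if cohort.shape[1] < 2:
        raise ValueError("cohort must have at least 2 samples")
    rows = []
    flag_rows = {}
    for gid in cohort.index:
        category = (
            str(classification.loc[gid, "category"])
            if gid in classification.index
            else "indeterminate"
        )
        pclass = "no_data"
        if protein_classes is not None and gid in protein_classes.index:
            pclass = str(protein_classes.loc[gid])
        res = call_ct_status(
            str(gid), cancer_type, category, pclass, cohort.loc[gid].to_numpy(),
            expression_threshold, ee_params, fraction_threshold, ct_categories,
        )
        rows.append(
            {
                "gene_id": res.gene_id,
                "cancer_type": cancer_type,
                "category": category,
                "protein_class": pclass,
                "expressed_fraction": res.expressed_fraction,
                "ee_fraction": res.ee_fraction,
                "is_ct": res.is_ct,
                "is_eectg": res.is_eectg,
                "is_eectp": res.is_eectp,
                "ee_floor": ee_params.floor,
                "ee_k": ee_params.k,
            }
        )
        flag_rows[str(gid)] = res.ee_flags
    calls = pd.DataFrame(rows).set_index("gene_id")
    flags = pd.DataFrame.from_dict(flag_rows, orient="index", columns=cohort.columns)
    return calls, flags
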