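"""CT-ncRNA identification and coding/ncRNA expression coupling.

Non-coding genes with high-confidence testis-specific expression
(categories C2/C4) that are expressed in at least 1% of a cancer cohort
are CT-ncRNAs, by direct analogy with coding CT genes.  CT-coding genes
are paired with CT-ncRNAs on the same chromosome whose gene bodies lie
within 100 kb (nearest-edge gap, strict; overlapping bodies count as
distance 0), and each pair's expression vectors are rank-correlated per
cancer type with BH adjustment.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ctcall, stats

__all__ = ["pair_genes", "correlate_pairs", "call_ct_ncrnas"]

MAX_PAIR_DISTANCE = 100_000


def _gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Nearest-edge gap between two half-open intervals; 0 on overlap."""
    return max(s2 - e1, s1 - e2, 0)


def pair_genes(
    coding: Sequence[str],
    ncrnas: Sequence[str],
    annotation: pd.DataFrame,
    max_distance: int = MAX_PAIR_DISTANCE,
) -> pd.DataFrame:
    """All (coding, ncRNA) pairs closer than ``max_distance`` on one chromosome.

    Genes absent from the annotation are skipped; the count of skipped
    ids is attached as ``DataFrame.attrs["n_skipped"]``.
    """
    ann = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    coding_ok = [g for g in coding if g in ann.index]
    nc_ok = [g for g in ncrnas if g in ann.index]
    n_skipped = (len(list(coding)) - len(coding_ok)) + (len(list(ncrnas)) - len(nc_ok))

    rows = []
    for c in coding_ok:
        crow = ann.loc[c]
        for n in nc_ok:
            nrow = ann.loc[n]
            if crow["chrom"] != nrow["chrom"]:
                continue
            d = _gap(int(crow["start"]), int(crow["end"]),
                     int(nrow["start"]), int(nrow["end"]))
            if d < max_distance:
                rows.append({"coding_gene": c, "ncrna_gene": n, "distance": d,
                             "chrom": crow["chrom"]})
    out = pd.DataFrame(rows, columns=["coding_gene", "ncrna_gene", "distance", "chrom"])
    out.attrs["n_skipped"] = n_skipped
    return out


def correlate_pairs(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    cancer_types: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Spearman correlation per pair within each cancer type, BH-adjusted.

    ``expression`` is genes x samples.  Pairs with a constant vector in
    a cancer type are marked not testable.
    """
    if cancer_types is None:
        cancer_types = pd.Series("all", index=expression.columns)
    rows = []
    for ctype in sorted(set(cancer_types)):
        samples = cancer_types.index[cancer_types == ctype]
        for pr in pairs.itertuples():
            x = expression.loc[pr.coding_gene, samples].to_numpy(dtype=float)
            y = expression.loc[pr.ncrna_gene, samples].to_numpy(dtype=float)
            t = stats.spearman_corr(x, y)
            testable = not np.isnan(t.statistic)
            rows.append(
                {"coding_gene": pr.coding_gene, "ncrna_gene": pr.ncrna_gene,
                 "cancer_type": ctype, "distance": pr.distance,
                 "rho": t.statistic, "p_value": t.p_value if testable else np.nan,
                 "testable": testable}
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    for ctype in sorted(set(cancer_types)):
        sel = (out["cancer_type"] == ctype) & out["testable"]
        if sel.any():
            out.loc[sel, "p_adjusted"] = stats.bh_adjust(out.loc[sel, "p_value"])
    return out


def call_ct_ncrnas(
    cohort: pd.DataFrame,
    classification: pd.DataFrame,
    expression_threshold: float = ctcall.EXPRESSION_THRESHOLD,
    fraction_threshold: float = ctcall.FRACTION_THRESHOLD,
    categories: frozenset = frozenset({"C2", "C4"}),
) -> list[str]:
    """CT-ncRNAs: testis-specific non-coding genes expressed in the cohort."""
    out = []
    for gid in cohort.index:
        if gid not in classification.index:
            continue
        if str(classification.loc[gid, "category"]) not in categories:
            continue
        frac, _ = ctcall.expression_fractions(
            cohort.loc[gid].to_numpy(), expression_threshold
        )
        if frac >= fraction_threshold:
            out.append(str(gid))
    return out
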