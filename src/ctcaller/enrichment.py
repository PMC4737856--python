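"""Proximity assignment of testis-specific regulatory elements (TSREs)
to genes, and enrichment of TSREs near high-confidence testis-specific
genes versus a background gene set.

Coordinates are 0-based half-open throughout.  Windows are strand-aware:
for promoter-like elements the window sits around the transcription
start site (TSS), which is the gene start on the + strand and the gene
end on the - strand; for distal elements (ncRNAs, enhancers) the window
is the gene body extended symmetrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from . import stats

__all__ = [
    "WindowSpec",
    "DEFAULT_WINDOWS",
    "AssignmentResult",
    "EnrichmentResult",
    "assign_elements",
    "enrichment_test",
]


@dataclass(frozen=True)
class WindowSpec:
    """Per-kind window. ``anchor`` is "tss" or "body".

    For a TSS anchor, ``upstream``/``downstream`` are measured from the
    TSS against/with the direction of transcription.  For a body anchor
    the gene body is extended by ``upstream`` on both sides.
    """

    anchor: str
    upstream: int
    downstream: int = 0

    def __post_init__(self):
        if self.anchor not in ("tss", "body"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be non-negative")


DEFAULT_WINDOWS = {
    "promoter": WindowSpec("tss", upstream=1000, downstream=100),
    "methylation_site": WindowSpec("tss", upstream=1000, downstream=100),
    "ncRNA": WindowSpec("body", upstream=100_000, downstream=100_000),
    "enhancer": WindowSpec("body", upstream=100_000, downstream=100_000),
}


@dataclass
class AssignmentResult:
    pairs: pd.DataFrame  # columns gene_id, element_id, kind
    n_skipped_elements: int = 0

    def genes_with(self, kind: str) -> set:
        sel = self.pairs[self.pairs["kind"] == kind]
        return set(sel["gene_id"])


@dataclass(frozen=True)
class EnrichmentResult:
    kind: str
    target_with: int
    target_without: int
    background_with: int
    background_without: int
    er: float
    ci_low: float
    ci_high: float
    test: stats.TestResult


def _gene_window(row, spec: WindowSpec) -> tuple[int, int]:
    start, end, strand = int(row.start), int(row.end), row.strand
    if spec.anchor == "body":
        return start - spec.upstream, end + spec.downstream
    tss = start if strand == "+" else end
    if strand == "+":
        return tss - spec.upstream, tss + spec.downstream
    return tss - spec.downstream, tss + spec.upstream


def assign_elements(
    annotation: pd.DataFrame,
    elements: pd.DataFrame,
    windows: Optional[dict] = None,
) -> AssignmentResult:
    """Map each regulatory element to the genes whose window it overlaps.

    ``annotation`` needs columns gene_id, chrom, start, end, strand;
    ``elements`` needs element_id, kind, chrom, start, end.  Overlap is
    any-base intersection of half-open intervals.  Elements on
    chromosomes absent from the annotation are skipped and counted.
    """
    windows = {**DEFAULT_WINDOWS, **(windows or {})}
    known_chroms = set(annotation["chrom"])

    # One interval tree of gene windows per (chrom, kind).
    trees: dict[tuple, IntervalTree] = {}
    for kind, spec in windows.items():
        for row in annotation.itertuples():
            lo, hi = _gene_window(row, spec)
            if hi <= lo:
                continue
            trees.setdefault((row.chrom, kind), IntervalTree()).addi(lo, hi, row.gene_id)

    records = []
    n_skipped = 0
    for el in elements.itertuples():
        if el.chrom not in known_chroms:
            n_skipped += 1
            continue
        if el.kind not in windows:
            raise ValueError(f"no window spec for element kind {el.kind!r}")
        tree = trees.get((el.chrom, el.kind))
        if tree is None:
            continue
        for iv in tree.overlap(int(el.start), int(el.end)):
            records.append((iv.data, el.element_id, el.kind))
    pairs = pd.DataFrame(records, columns=["gene_id", "element_id", "kind"])
    pairs = pairs.sort_values(["kind", "gene_id", "element_id"]).reset_index(drop=True)
    return AssignmentResult(pairs, n_skipped)


def enrichment_test(
    target_genes: set,
    background_genes: set,
    mapping: AssignmentResult,
    kind: str,
) -> EnrichmentResult:
    """Enrichment ratio of element-bearing genes in target vs background.

    ER = (fraction of target genes with >= 1 element of ``kind``) /
    (fraction of background genes with >= 1); ER = 1 means no
    enrichment.  Significance is the two-sided Fisher exact test on the
    2x2 table; the 95% CI comes from the log-ratio normal approximation.
    A zero background fraction yields ER = inf with an undefined CI.
    """
    target_genes = set(target_genes)
    background_genes = set(background_genes)
    if not target_genes or not background_genes:
        raise ValueError("target and background must be non-empty")
    if target_genes & background_genes:
        raise ValueError("target and background gene sets overlap")

    hit = mapping.genes_with(kind)
    a = len(target_genes & hit)
    b = len(target_genes) - a
    c = len(background_genes & hit)
    d = len(background_genes) - c

    test = stats.fisher_2x2([[a, b], [c, d]])

    n1, n2 = a + b, c + d
    p1, p2 = a / n1, c / n2
    if p2 == 0:
        er, ci_low, ci_high = math.inf, math.nan, math.nan
    else:
        er = p1 / p2
        if a == 0:
            ci_low, ci_high = 0.0, math.nan
        else:
            se = math.sqrt((1 - p1) / (n1 * p1) + (1 - p2) / (n2 * p2))
            z = sps.norm.ppf(0.975)
            ci_low = er * math.exp(-z * se)
            ci_high = er * math.exp(z * se)
    return EnrichmentResult(kind, a, b, c, d, er, ci_low, ci_high, test)
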