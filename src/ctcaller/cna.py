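"""Copy-number burden and allele-specific imbalance scoring.

Two segment representations are consumed:

* log-ratio segments (SEG-like; Seg.CN per segment) for the global
  burden of focal copy-number aberration: the summed length of segments
  whose Seg.CN strictly exceeds the gain cutoff (+0.2) or falls strictly
  below the loss cutoff (-0.2);
* allele-specific segments (major/minor copies nA >= nB) classified
  into mutually exclusive states at a given ploidy (default 2):

  - normal:  total = ploidy and nA = nB (diploid heterozygous);
  - CnLOH:   total = ploidy, one allele lost entirely (nB = 0, nA > 0);
  - AiCNA:   allele-imbalanced aberration (nA != nB, otherwise);
  - AbCNA:   allele-balanced aberration (total != ploidy, nA = nB);
    this includes homozygous deletion (0, 0), which is flagged.

Per-sample scores are genome-length fractions of each state; the
allelic-imbalance score S_Ai = S_AiCNA + S_CnLOH captures all
imbalance events.  Length fractions make the scores additive and
invariant to splitting a segment into adjacent pieces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import stats
from .mutassoc import AssociationResult

__all__ = [
    "ImbalanceScore",
    "focal_burden",
    "classify_allele_segment",
    "imbalance_scores",
    "activation_vs_instability",
]

GAIN_CUT = 0.2
LOSS_CUT = -0.2


@dataclass(frozen=True)
class ImbalanceScore:
    sample_id: str
    s_aicna: float
    s_abcna: float
    s_cnloh: float
    s_ai: float
    has_homozygous_deletion: bool = False

    def __post_init__(self):
        for name in ("s_aicna", "s_abcna", "s_cnloh", "s_ai"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.s_ai - (self.s_aicna + self.s_cnloh)) > 1e-12:
            raise ValueError("s_ai must equal s_aicna + s_cnloh")


def _check_non_overlapping(segments: pd.DataFrame) -> None:
    for chrom, grp in segments.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"] >= g["end"]).any():
            raise ValueError(f"segment with start >= end on {chrom}")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments on {chrom}")


def focal_burden(
    segments: pd.DataFrame,
    gain_cut: float = GAIN_CUT,
    loss_cut: float = LOSS_CUT,
) -> int:
    """Total aberrant length (bp) for one sample's log-ratio segments.

    ``segments`` needs columns chrom, start, end, seg_cn.  Cutoffs are
    strict: a segment exactly at a cutoff is not counted.
    """
    if len(segments) == 0:
        return 0
    _check_non_overlapping(segments)
    cn = segments["seg_cn"].to_numpy(dtype=float)
    lengths = (segments["end"] - segments["start"]).to_numpy()
    aberrant = (cn > gain_cut) | (cn < loss_cut)
    return int(lengths[aberrant].sum())


def classify_allele_segment(nA: int, nB: int, ploidy: int = 2) -> str:
    """Classify one allele-specific segment into normal/AiCNA/AbCNA/CnLOH."""
    if nB > nA:
        raise ValueError("requires nA >= nB")
    if nB < 0:
        raise ValueError("copy numbers must be non-negative")
    total = nA + nB
    if total == ploidy:
        if nA == nB:
            return "normal"
        if nB == 0:
            return "CnLOH"
        return "AiCNA"  # only reachable at ploidy > 2
    return "AiCNA" if nA != nB else "AbCNA"


def imbalance_scores(
    segments: pd.DataFrame,
    genome_length: int,
    sample_id: str = "",
    ploidy: int = 2,
) -> ImbalanceScore:
    """Length-fraction scores for one sample's allele-specific segments.

    ``segments`` needs columns chrom, start, end, nA, nB.  Uncovered
    genome is treated as normal.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    lengths = {"AiCNA": 0, "AbCNA": 0, "CnLOH": 0, "normal": 0}
    homdel = False
    if len(segments):
        _check_non_overlapping(segments)
        for row in segments.itertuples():
            cls = classify_allele_segment(int(row.nA), int(row.nB), ploidy)
            lengths[cls] += int(row.end - row.start)
            if row.nA == 0 and row.nB == 0:
                homdel = True
    covered = sum(lengths.values())
    if covered > genome_length:
        raise ValueError("covered segment length exceeds genome length")
    s_ai = (lengths["AiCNA"] + lengths["CnLOH"]) / genome_length
    return ImbalanceScore(
        sample_id,
        lengths["AiCNA"] / genome_length,
        lengths["AbCNA"] / genome_length,
        lengths["CnLOH"] / genome_length,
        s_ai,
        homdel,
    )


def score_table(
    allele_segments: pd.DataFrame, genome_length: int, ploidy: int = 2
) -> pd.DataFrame:
    """Per-sample imbalance scores from a multi-sample allele-segment table."""
    rows = []
    for sample, grp in allele_segments.groupby("sample_id"):
        sc = imbalance_scores(grp, genome_length, str(sample), ploidy)
        rows.append(
            {"sample_id": sc.sample_id, "s_aicna": sc.s_aicna,
             "s_abcna": sc.s_abcna, "s_cnloh": sc.s_cnloh, "s_ai": sc.s_ai,
             "has_homozygous_deletion": sc.has_homozygous_deletion}
        )
    return pd.DataFrame(rows).set_index("sample_id").sort_index()


def burden_table(
    segments: pd.DataFrame, gain_cut: float = GAIN_CUT, loss_cut: float = LOSS_CUT
) -> pd.Series:
    """Per-sample focal burden from a multi-sample log-ratio segment table."""
    out = {
        str(sample): focal_burden(grp, gain_cut, loss_cut)
        for sample, grp in segments.groupby("sample_id")
    }
    return pd.Series(out, name="focal_burden").sort_index()


def activation_vs_instability(
    values: pd.Series,
    activation: pd.Series,
    kind: str = "expression",
) -> AssociationResult:
    """Associate genome-instability measures with gene activation.

    ``kind="expression"``: Spearman correlation of a continuous
    expression vector (``activation``) with per-sample burdens/scores
    (``values``).  ``kind="ee"``: rank-sum of ``values`` between EE and
    non-EE samples (``activation`` boolean).
    """
    df = pd.DataFrame({"v": values, "a": activation}).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 samples")
    if kind == "expression":
        t = stats.spearman_corr(df["a"].to_numpy(), df["v"].to_numpy())
        return AssociationResult("cohort", t.statistic, t, len(df))
    if kind == "ee":
        flags = df["a"].astype(bool).to_numpy()
        if flags.all() or not flags.any():
            raise ValueError("need both EE and non-EE samples")
        t = stats.rank_sum_test(df.loc[flags, "v"].to_numpy(),
                                df.loc[~flags, "v"].to_numpy())
        return AssociationResult("cohort", t.statistic, t, len(df))
    raise ValueError(f"unknown kind {kind!r}")
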