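"""Tissue-specificity scoring (SPM) and gene/protein classification.

The specificity measure (SPM) of a gene for a target tissue is the
cosine between its expression vector across tissues and the unit vector
of that tissue::

    SPM = x_target / sqrt(sum_t x_t**2)

It lies in [0, 1], equals 1 iff only the target tissue is expressed, is
invariant to rescaling the whole vector, and is 0 by convention for an
all-zero vector.

Genes are assigned to one of seven mutually exclusive categories from
their SPM values in three independent normal-tissue panels (GTEx-style,
HBM-style, NJMU-style) plus a transcript-level panel:

* C1 / C2 - high-confidence testis-specific coding / non-coding genes
  (SPM > 0.9 in all three panels; coding genes known as CT genes are
  rescued into C1 when SPM_GTEx = 0 but both other panels exceed 0.9
  and the gene has identical-sequence copies);
* C3 / C4 - moderate confidence (GTEx plus exactly one other panel);
* C5 - low confidence (GTEx only);
* C6a / C6b - not testis-specific at the gene level, with (C6a) or
  without (C6b) at least one testis-specific transcript.

Proteins are classified from peptide evidence: TSP (testis-specific
protein, unique-peptide SPM > 0.9), testis-specific-peptide (no unique
peptides but at least one testis-specific peptide), no-data, non-TSP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPM_THRESHOLD",
    "SpecificityProfile",
    "GeneClassification",
    "compute_spm",
    "spm_profile",
    "classify_gene",
    "classify_protein",
    "classify_genes",
    "classify_proteins",
]

SPM_THRESHOLD = 0.9

CATEGORIES = ("C1", "C2", "C3", "C4", "C5", "C6a", "C6b")
PROTEIN_CLASSES = ("TSP", "testis_specific_peptide", "no_data", "non_TSP")


@dataclass(frozen=True)
class SpecificityProfile:
    gene_id: str
    spm_gtex: Optional[float]
    spm_hbm: Optional[float]
    spm_njmu: Optional[float]
    spm_transcript_max: Optional[float] = None

    def __post_init__(self):
        for name in ("spm_gtex", "spm_hbm", "spm_njmu", "spm_transcript_max"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    biotype: str  # {"coding", "noncoding"}
    category: str  # C1..C6b or "indeterminate"
    known_ct: bool = False
    protein_class: str = "no_data"


def compute_spm(abundances: Sequence[float], tissues: Sequence[str],
                target_tissue: str = "testis") -> float:
    """SPM of one expression vector for ``target_tissue``.

    Raises if the target tissue is absent or any abundance is negative.
    Returns 0.0 for an all-zero vector.
    """
    x = np.asarray(abundances, dtype=float)
    tissues = list(tissues)
    if x.size == 0 or x.size != len(tissues):
        raise ValueError("abundances and tissues must be non-empty and equal length")
    if np.any(x < 0):
        raise ValueError("negative abundance")
    if target_tissue not in tissues:
        raise ValueError(f"target tissue {target_tissue!r} not in panel")
    norm = math.sqrt(float((x.astype(float) ** 2).sum()))
    if norm == 0.0:
        return 0.0
    return float(x[tissues.index(target_tissue)] / norm)


def spm_profile(matrix: pd.DataFrame, target_tissue: str = "testis") -> pd.Series:
    """Vectorised SPM per row of a genes x tissues matrix."""
    if target_tissue not in matrix.columns:
        raise ValueError(f"target tissue {target_tissue!r} not in panel")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate entity ids in expression matrix")
    x = matrix.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundance")
    norm = np.sqrt((x**2).sum(axis=1))
    target = matrix[target_tissue].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        spm = np.where(norm > 0, target / np.where(norm > 0, norm, 1.0), 0.0)
    return pd.Series(spm, index=matrix.index, name="spm")


def _above(v: Optional[float]) -> bool:
    return v is not None and not math.isnan(v) and v > SPM_THRESHOLD


def classify_gene(
    profile: SpecificityProfile,
    biotype: str,
    known_ct: bool = False,
    has_identical_copies: bool = False,
) -> GeneClassification:
    """Assign exactly one C1-C6b category from a specificity profile.

    A missing SPM that the rules need yields category ``indeterminate``
    rather than a silent default.
    """
    if biotype not in ("coding", "noncoding"):
        raise ValueError(f"unknown biotype {biotype!r}")
    g, h, nj = profile.spm_gtex, profile.spm_hbm, profile.spm_njmu
    tmax = profile.spm_transcript_max

    def _missing(v):
        return v is None or (isinstance(v, float) and math.isnan(v))

    category = "indeterminate"
    if (
        known_ct
        and biotype == "coding"
        and not _missing(g)
        and g == 0.0
        and _above(h)
        and _above(nj)
        and has_identical_copies
    ):
        # Rescue rule for known CT genes silenced in the reference panel by
        # multi-copy identical sequences defeating unique alignment.
        category = "C1"
    elif _missing(g) or _missing(h) or _missing(nj):
        category = "indeterminate"
    elif _above(g):
        if _above(h) and _above(nj):
            category = "C1" if biotype == "coding" else "C2"
        elif _above(h) or _above(nj):
            category = "C3" if biotype == "coding" else "C4"
        else:
            category = "C5"
    else:
        if _missing(tmax):
            category = "indeterminate"
        else:
            category = "C6a" if _above(tmax) else "C6b"
    return GeneClassification(profile.gene_id, biotype, category, known_ct)


def classify_protein(
    protein_spm: Optional[float],
    peptide_spms: Sequence[float],
    has_unique_peptides: bool,
) -> str:
    """Classify a protein from unique-peptide and peptide-level SPM evidence."""
    if has_unique_peptides and protein_spm is None:
        raise ValueError("protein_spm required when unique peptides exist")
    if not has_unique_peptides and protein_spm is not None:
        raise ValueError("protein_spm given without unique peptides")
    if has_unique_peptides:
        return "TSP" if protein_spm > SPM_THRESHOLD else "non_TSP"
    if len(peptide_spms) == 0:
        return "no_data"
    if any(p > SPM_THRESHOLD for p in peptide_spms):
        return "testis_specific_peptide"
    return "non_TSP"


def classify_genes(
    panels: dict[str, pd.DataFrame],
    transcript_panel: Optional[pd.DataFrame] = None,
    transcript_gene_map: Optional[pd.Series] = None,
    biotypes: Optional[pd.Series] = None,
    known_ct: Optional[set] = None,
    identical_copies: Optional[set] = None,
    target_tissue: str = "testis",
) -> pd.DataFrame:
    """Classify a whole gene universe.

    ``panels`` maps the dataset keys ``gtex``/``hbm``/``njmu`` to gene x
    tissue expression matrices.  ``transcript_panel`` is a transcript x
    tissue matrix for the reference panel, with ``transcript_gene_map``
    giving the parent gene of each transcript.  Returns a DataFrame
    indexed by gene id with the SPM columns and the assigned category.
    """
    required = {"gtex", "hbm", "njmu"}
    if set(panels) != required:
        raise ValueError(f"panels must have keys {sorted(required)}")
    known_ct = known_ct or set()
    identical_copies = identical_copies or set()

    genes = panels["gtex"].index
    spms = {}
    for key in ("gtex", "hbm", "njmu"):
        spms[key] = spm_profile(panels[key], target_tissue).reindex(genes)

    tmax = pd.Series(np.nan, index=genes)
    if transcript_panel is not None:
        if transcript_gene_map is None:
            raise ValueError("transcript_gene_map required with transcript_panel")
        tspm = spm_profile(transcript_panel, target_tissue)
        grouped = tspm.groupby(transcript_gene_map.reindex(tspm.index)).max()
        tmax = grouped.reindex(genes)

    if biotypes is None:
        raise ValueError("biotypes required")
    rows = []
    for gid in genes:
        prof = SpecificityProfile(
            gene_id=str(gid),
            spm_gtex=_nan_to_none(spms["gtex"].get(gid)),
            spm_hbm=_nan_to_none(spms["hbm"].get(gid)),
            spm_njmu=_nan_to_none(spms["njmu"].get(gid)),
            spm_transcript_max=_nan_to_none(tmax.get(gid)),
        )
        cls = classify_gene(
            prof,
            biotype=str(biotypes.get(gid)),
            known_ct=gid in known_ct,
            has_identical_copies=gid in identical_copies,
        )
        rows.append(
            {
                "gene_id": str(gid),
                "biotype": cls.biotype,
                "spm_gtex": spms["gtex"].get(gid),
                "spm_hbm": spms["hbm"].get(gid),
                "spm_njmu": spms["njmu"].get(gid),
                "spm_transcript_max": tmax.get(gid),
                "category": cls.category,
                "known_ct": cls.known_ct,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _nan_to_none(v):
    if v is None:
        return None
    v = float(v)
    return None if math.isnan(v) else v


def classify_proteins(
    peptides: pd.DataFrame,
    tissue_columns: Sequence[str],
    target_tissue: str = "testis",
) -> pd.DataFrame:
    """Classify every protein appearing in a peptide abundance table.

    ``peptides`` must have columns ``peptide_id``, ``protein_ids`` (a
    semicolon-joined list; a single entry marks a unique peptide) plus
    one abundance column per tissue.  Protein-level abundance is the sum
    of its unique peptides' abundances per tissue.
    """
    tissue_columns = list(tissue_columns)
    pep = peptides.copy()
    pep["_proteins"] = pep["protein_ids"].str.split(";")
    pep["_unique"] = pep["_proteins"].str.len() == 1

    pep_spm = spm_profile(
        pep.set_index("peptide_id")[tissue_columns], target_tissue
    )

    protein_rows: dict[str, dict] = {}
    for _, row in pep.iterrows():
        for pid in row["_proteins"]:
            rec = protein_rows.setdefault(
                pid, {"unique_abund": np.zeros(len(tissue_columns)), "has_unique": False,
                      "peptide_spms": []}
            )
            rec["peptide_spms"].append(float(pep_spm[row["peptide_id"]]))
            if row["_unique"]:
                rec["has_unique"] = True
                rec["unique_abund"] += row[tissue_columns].to_numpy(dtype=float)

    out = []
    for pid, rec in sorted(protein_rows.items()):
        if rec["has_unique"]:
            pspm = compute_spm(rec["unique_abund"], tissue_columns, target_tissue)
        else:
            pspm = None
        pclass = classify_protein(pspm, rec["peptide_spms"], rec["has_unique"])
        out.append(
            {
                "protein_id": pid,
                "protein_spm": np.nan if pspm is None else pspm,
                "n_peptides": len(rec["peptide_spms"]),
                "has_unique_peptides": rec["has_unique"],
                "protein_class": pclass,
            }
        )
    return pd.DataFrame(out).set_index("protein_id")
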