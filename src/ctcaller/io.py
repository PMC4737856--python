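"""Readers and writers for the pipeline's file formats.

Internal coordinates are 0-based half-open everywhere; conversions
happen only here.  GTF is 1-based closed on disk, BED and SEG-like
tables are 0-based half-open.  All matrices are TSV with the entity id
in the first column and one column per sample/tissue.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .synthdata import Annotation, GroundTruth

PathLike = Union[str, Path]

FLOAT_FORMAT = "%.6g"

_BIOTYPE_TO_GTF = {"coding": "protein_coding", "noncoding": "lincRNA"}
_GTF_TO_BIOTYPE = {"protein_coding": "coding"}


class InputFormatError(ValueError):
    """Malformed input file; message names file and problem."""


# --------------------------------------------------------------------- GTF


def write_gtf(annotation: Annotation, path: PathLike) -> None:
    lines = []
    for row in annotation.genes.itertuples():
        attrs = (
            f'gene_id "{row.gene_id}"; '
            f'gene_biotype "{_BIOTYPE_TO_GTF[row.biotype]}";'
        )
        lines.append(
            "\t".join(
                [row.chrom, "synth", "gene", str(row.start + 1), str(row.end),
                 ".", row.strand, ".", attrs]
            )
        )
    for row in annotation.transcripts.itertuples():
        attrs = (
            f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}";'
        )
        lines.append(
            "\t".join(
                [row.chrom, "synth", "transcript", str(row.start + 1), str(row.end),
                 ".", row.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: PathLike) -> Annotation:
    """Parse a GTF into the internal annotation (0-based half-open)."""
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - error path
        raise InputFormatError(f"{path}: not parseable as GTF ({exc})") from exc

    gene_rows, tx_rows = [], []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        biotype_raw = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
        gene_rows.append(
            {
                "gene_id": feat.attributes["gene_id"][0],
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
                "biotype": _GTF_TO_BIOTYPE.get(biotype_raw, "noncoding"),
            }
        )
    for feat in db.features_of_type("transcript", order_by=("seqid", "start")):
        tx_rows.append(
            {
                "transcript_id": feat.attributes["transcript_id"][0],
                "gene_id": feat.attributes["gene_id"][0],
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    genes = pd.DataFrame(gene_rows)
    if genes.empty:
        raise InputFormatError(f"{path}: no gene features found")
    chrom_lengths = {
        c: int(g["end"].max()) + 1 for c, g in genes.groupby("chrom")
    }
    return Annotation(genes, pd.DataFrame(tx_rows), chrom_lengths)


# --------------------------------------------------------------------- BED


def write_bed(elements: pd.DataFrame, path: PathLike) -> None:
    """Element track as BED6 plus a 7th ``kind`` column (0-based half-open)."""
    out = elements[["chrom", "start", "end", "element_id"]].copy()
    out["score"] = 0
    out["strand"] = "."
    out["kind"] = elements["kind"]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "element_id", "score", "strand", "kind"],
        )
    except Exception as exc:
        raise InputFormatError(f"{path}: not parseable as BED ({exc})") from exc
    if df[["start", "end"]].isna().any().any():
        raise InputFormatError(f"{path}: missing coordinates")
    df["testis_specific"] = True
    return df[["element_id", "kind", "chrom", "start", "end", "testis_specific"]]


# ---------------------------------------------------------------- matrices


def write_matrix(matrix: pd.DataFrame, path: PathLike, index_label: str = "gene_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FORMAT)


def read_matrix(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise InputFormatError(f"{path}: not parseable as a TSV matrix ({exc})") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise InputFormatError(f"{path}: duplicate entity id {dup!r}")
    return df


def write_table(df: pd.DataFrame, path: PathLike, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", **kwargs)


# --------------------------------------------------------------------- MAF


MAF_COLUMNS = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]


def write_maf(maf: pd.DataFrame, path: PathLike) -> None:
    maf[MAF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_maf(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing MAF columns {missing}")
    return df


# --------------------------------------------------------------------- SEG


def write_seg(segments: pd.DataFrame, path: PathLike) -> None:
    out = segments.rename(columns={"seg_cn": "Seg.CN"})
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_seg(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "chrom", "start", "end", "Seg.CN"}
    if not required.issubset(df.columns):
        raise InputFormatError(f"{path}: missing SEG columns {sorted(required - set(df.columns))}")
    return df.rename(columns={"Seg.CN": "seg_cn"})


def write_allele_seg(segments: pd.DataFrame, path: PathLike) -> None:
    segments[["sample_id", "chrom", "start", "end", "nA", "nB"]].to_csv(
        path, sep="\t", index=False
    )


def read_allele_seg(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "chrom", "start", "end", "nA", "nB"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"{path}: missing allele-SEG columns {sorted(required - set(df.columns))}"
        )
    return df


# ------------------------------------------------------------ ground truth


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    payload = {
        "tsg_gene_ids": sorted(truth.tsg_gene_ids),
        "ee_gene_ids": sorted(truth.ee_gene_ids),
        "activation": {
            g: [bool(v) for v in truth.activation.loc[g]]
            for g in truth.activation.index
        },
        "activation_samples": list(truth.activation.columns),
        "exclusive_mutation_gene": truth.exclusive_mutation_gene,
        "smg_genes": list(truth.smg_genes),
        "hypomethylated_gene_ids": sorted(truth.hypomethylated_gene_ids),
        "imbalance_driver_gene": truth.imbalance_driver_gene,
        "ncrna_pairs": [list(p) for p in truth.ncrna_pairs],
        "c6a_gene_ids": sorted(truth.c6a_gene_ids),
        "shared_only_proteins": sorted(truth.shared_only_proteins),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_ground_truth(path: PathLike) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    activation = pd.DataFrame(
        {g: payload["activation"][g] for g in sorted(payload["activation"])},
    ).T
    activation.columns = payload["activation_samples"]
    return GroundTruth(
        tsg_gene_ids=set(payload["tsg_gene_ids"]),
        ee_gene_ids=set(payload["ee_gene_ids"]),
        activation=activation.astype(bool),
        exclusive_mutation_gene=payload["exclusive_mutation_gene"],
        smg_genes=list(payload["smg_genes"]),
        hypomethylated_gene_ids=set(payload["hypomethylated_gene_ids"]),
        imbalance_driver_gene=payload["imbalance_driver_gene"],
        ncrna_pairs=[tuple(p) for p in payload["ncrna_pairs"]],
        c6a_gene_ids=set(payload["c6a_gene_ids"]),
        shared_only_proteins=set(payload["shared_only_proteins"]),
    )
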