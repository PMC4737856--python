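"""End-to-end orchestration: simulate -> classify -> enrich -> call ->
associate stages, with per-stage outputs and a run manifest.

Stages are independent and skippable: a stage whose inputs are absent is
recorded as skipped in the manifest and the rest of the run proceeds.
The manifest also echoes every threshold and the input checksums so a
run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, cna, ctcall, enrichment, io, methassoc, mutassoc, ncrna, specificity
from .synthdata import Annotation, SimulationConfig

log = logging.getLogger("ctcaller")

STAGES = ("simulate", "classify", "enrich", "call", "mut-assoc", "meth-assoc",
          "cna-score", "ncrna-pairs")


class PipelineValidationError(ValueError):
    """Configuration or input validation failure (CLI exit code 2)."""


@dataclass
class Thresholds:
    spm: float = 0.9
    expression: float = 5.0
    fraction: float = 0.01
    ee_floor: float = 32.0
    ee_k: float = 3.0
    gain_cut: float = 0.2
    loss_cut: float = -0.2
    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    distal_window: int = 100_000
    max_pair_distance: int = 100_000

    def validate(self) -> None:
        if not (0.0 < self.spm <= 1.0):
            raise PipelineValidationError(f"threshold spm={self.spm} outside (0, 1]")
        if self.expression < 0 or self.ee_floor < 0 or self.ee_k < 0:
            raise PipelineValidationError("expression/ee thresholds must be non-negative")
        if not (0.0 <= self.fraction <= 1.0):
            raise PipelineValidationError("fraction threshold outside [0, 1]")
        if self.loss_cut >= self.gain_cut:
            raise PipelineValidationError("loss_cut must be below gain_cut")
        if self.max_pair_distance <= 0 or self.distal_window <= 0:
            raise PipelineValidationError("windows must be positive")


@dataclass
class PipelineConfig:
    outdir: str = "ctcaller_out"
    seed: int = 0
    cancer_type: str = "SYNTH"
    log_level: str = "INFO"
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulate: Optional[dict] = None  # SimulationConfig overrides, or None
    inputs: dict = field(default_factory=dict)  # name -> path
    exclude_genes: list = field(default_factory=list)  # dropped from mutation ratios
    nonsilent_only: bool = False  # drop Silent variants from mutation analyses
    cna_target_gene: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=thr, **raw)

    def validate(self) -> None:
        self.thresholds.validate()
        if self.seed < 0:
            raise PipelineValidationError("seed must be non-negative")

    def sim_config(self) -> SimulationConfig:
        overrides = dict(self.simulate or {})
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("ee_floor", self.thresholds.ee_floor)
        try:
            return SimulationConfig(**overrides)
        except TypeError as exc:
            raise PipelineValidationError(f"bad simulate section: {exc}") from exc


INPUT_FILES = {
    "gtf": "annotation.gtf",
    "elements_bed": "elements.bed",
    "panel_gtex": "panel_gtex.tsv",
    "panel_hbm": "panel_hbm.tsv",
    "panel_njmu": "panel_njmu.tsv",
    "transcript_panel": "transcript_gtex.tsv",
    "peptides": "peptides.tsv",
    "cohort": "tumor_expression.tsv",
    "maf": "mutations.maf.tsv",
    "smg_list": "smg_list.txt",
    "methylation": "methylation_beta.tsv",
    "seg": "segments_logratio.seg.tsv",
    "allele_seg": "segments_allele.seg.tsv",
    "ground_truth": "ground_truth.json",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _have(cfg: PipelineConfig, *names: str) -> bool:
    return all(
        name in cfg.inputs and Path(cfg.inputs[name]).exists() for name in names
    )


def run_pipeline(config: PipelineConfig, stages: Optional[list] = None) -> dict:
    """Run the requested stages (all by default); returns output paths."""
    config.validate()
    stages = list(stages or STAGES)
    for s in stages:
        if s not in STAGES:
            raise PipelineValidationError(f"unknown stage {s!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "cancer_type": config.cancer_type,
        "thresholds": {f.name: getattr(config.thresholds, f.name)
                       for f in dc_fields(Thresholds)},
        "stages_run": [],
        "stages_skipped": {},
        "counts": {},
        "inputs": {},
    }
    outputs: dict = {}

    if "simulate" in stages and config.simulate is not None:
        _stage_simulate(config, outdir, manifest)
        manifest["stages_run"].append("simulate")

    annotation = io.read_gtf(config.inputs["gtf"]) if _have(config, "gtf") else None

    classification = None
    if "classify" in stages:
        needed = ("panel_gtex", "panel_hbm", "panel_njmu")
        if _have(config, *needed) and annotation is not None:
            classification = _stage_classify(config, annotation, outdir, manifest)
            outputs["classification"] = outdir / "classification.tsv"
            manifest["stages_run"].append("classify")
        else:
            manifest["stages_skipped"]["classify"] = "missing expression panels or annotation"
    if classification is None and (outdir / "classification.tsv").exists():
        classification = io.read_table(outdir / "classification.tsv", index_col=0)

    if "enrich" in stages:
        if classification is not None and annotation is not None and _have(config, "elements_bed"):
            _stage_enrich(config, annotation, classification, outdir, manifest)
            outputs["enrichment"] = outdir / "enrichment.tsv"
            manifest["stages_run"].append("enrich")
        else:
            manifest["stages_skipped"]["enrich"] = "missing classification or element track"

    calls = flags = None
    if "call" in stages:
        if classification is not None and _have(config, "cohort"):
            calls, flags = _stage_call(config, classification, outdir, manifest)
            outputs["ct_calls"] = outdir / "ct_calls.tsv"
            manifest["stages_run"].append("call")
        else:
            manifest["stages_skipped"]["call"] = "missing classification or cohort"
    if calls is None and (outdir / "ct_calls.tsv").exists():
        calls = io.read_table(outdir / "ct_calls.tsv", index_col=0)
        flags = io.read_matrix(outdir / "ee_flags.tsv").astype(bool)

    if "mut-assoc" in stages:
        if calls is not None and _have(config, "maf", "smg_list"):
            _stage_mutassoc(config, calls, flags, outdir, manifest)
            outputs["mut_assoc"] = outdir / "mut_assoc_cohort.tsv"
            manifest["stages_run"].append("mut-assoc")
        else:
            manifest["stages_skipped"]["mut-assoc"] = "missing CT calls or mutation inputs"

    if "meth-assoc" in stages:
        if calls is not None and _have(config, "methylation"):
            _stage_methassoc(config, calls, flags, outdir, manifest)
            outputs["meth_assoc"] = outdir / "meth_assoc_cohort.tsv"
            manifest["stages_run"].append("meth-assoc")
        else:
            manifest["stages_skipped"]["meth-assoc"] = "missing CT calls or methylation matrix"

    if "cna-score" in stages:
        if _have(config, "seg", "allele_seg"):
            _stage_cna(config, calls, flags, outdir, manifest)
            outputs["cna_scores"] = outdir / "cna_scores.tsv"
            manifest["stages_run"].append("cna-score")
        else:
            manifest["stages_skipped"]["cna-score"] = "missing segment tables"

    if "ncrna-pairs" in stages:
        if calls is not None and classification is not None and annotation is not None and _have(config, "cohort"):
            _stage_ncrna(config, annotation, classification, calls, outdir, manifest)
            outputs["ncrna_pairs"] = outdir / "ncrna_pairs.tsv"
            manifest["stages_run"].append("ncrna-pairs")
        else:
            manifest["stages_skipped"]["ncrna-pairs"] = "missing CT calls or annotation"

    for name, path in sorted(config.inputs.items()):
        p = Path(path)
        if p.exists():
            try:
                shown = str(p.resolve().relative_to(outdir.resolve()))
            except ValueError:
                shown = str(p)
            manifest["inputs"][name] = {"path": shown, "sha256": _sha256(p)}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    outputs["manifest"] = outdir / "manifest.json"
    return outputs


# ----------------------------------------------------------------- stages


def _stage_simulate(config: PipelineConfig, outdir: Path, manifest: dict) -> None:
    from . import synthdata

    sim = config.sim_config()
    indir = outdir / "inputs"
    indir.mkdir(exist_ok=True)
    annotation, elements = synthdata.generate_reference(sim)
    panels = synthdata.generate_normal_panels(sim, annotation)
    tumor = synthdata.generate_tumor_cohort(sim, annotation)

    paths = {k: indir / v for k, v in INPUT_FILES.items()}
    io.write_gtf(annotation, paths["gtf"])
    io.write_bed(elements, paths["elements_bed"])
    for key in ("gtex", "hbm", "njmu"):
        io.write_matrix(panels.panels[key], paths[f"panel_{key}"])
    io.write_matrix(panels.transcript_panel, paths["transcript_panel"],
                    index_label="transcript_id")
    io.write_table(panels.peptides, paths["peptides"], index=False)
    io.write_matrix(tumor.expression, paths["cohort"])
    io.write_maf(tumor.mutations, paths["maf"])
    paths["smg_list"].write_text("\n".join(tumor.truth.smg_genes) + "\n")
    io.write_matrix(tumor.methylation, paths["methylation"])
    io.write_seg(tumor.segments_logratio, paths["seg"])
    io.write_allele_seg(tumor.segments_allele, paths["allele_seg"])
    io.write_ground_truth(tumor.truth, paths["ground_truth"])

    config.inputs = {k: str(v) for k, v in paths.items()}
    manifest["counts"]["simulated_genes"] = int(sim.n_genes)
    manifest["counts"]["simulated_samples"] = int(sim.cohort_size)
    manifest["simulated_genome_length"] = int(sim.genome_length)


def _stage_classify(config, annotation: Annotation, outdir: Path, manifest: dict) -> pd.DataFrame:
    panels = {k: io.read_matrix(config.inputs[f"panel_{k}"]) for k in ("gtex", "hbm", "njmu")}
    tx_panel = None
    tx_map = None
    if _have(config, "transcript_panel"):
        tx_panel = io.read_matrix(config.inputs["transcript_panel"])
        tx_map = pd.Series(
            annotation.transcripts["gene_id"].to_numpy(),
            index=annotation.transcripts["transcript_id"].to_numpy(),
        )
    biotypes = pd.Series(
        annotation.genes["biotype"].to_numpy(), index=annotation.genes["gene_id"].to_numpy()
    )
    classification = specificity.classify_genes(
        panels, tx_panel, tx_map, biotypes=biotypes
    )

    classification["protein_class"] = "no_data"
    if _have(config, "peptides"):
        pep = io.read_table(config.inputs["peptides"])
        tissue_cols = [c for c in pep.columns if c not in ("peptide_id", "protein_ids")]
        prot = specificity.classify_proteins(pep, tissue_cols)
        shared = prot["protein_class"].reindex(classification.index)
        classification.loc[shared.notna(), "protein_class"] = shared.dropna()

    io.write_table(classification, outdir / "classification.tsv")
    manifest["counts"]["genes_classified"] = int(len(classification))
    manifest["counts"]["category_counts"] = (
        classification["category"].value_counts().sort_index().astype(int).to_dict()
    )
    return classification


def _stage_enrich(config, annotation, classification, outdir, manifest) -> None:
    elements = io.read_bed(config.inputs["elements_bed"])
    thr = config.thresholds
    windows = {
        "promoter": enrichment.WindowSpec("tss", thr.promoter_upstream, thr.promoter_downstream),
        "methylation_site": enrichment.WindowSpec("tss", thr.promoter_upstream, thr.promoter_downstream),
        "ncRNA": enrichment.WindowSpec("body", thr.distal_window, thr.distal_window),
        "enhancer": enrichment.WindowSpec("body", thr.distal_window, thr.distal_window),
    }
    mapping = enrichment.assign_elements(annotation.genes, elements, windows)
    coding = classification[classification["biotype"] == "coding"]
    target = set(coding.index[coding["category"] == "C1"])
    background = set(coding.index[coding["category"] == "C6b"])
    rows = []
    for kind in sorted(elements["kind"].unique()):
        res = enrichment.enrichment_test(target, background, mapping, kind)
        rows.append(
            {"kind": kind, "target_with": res.target_with, "target_without": res.target_without,
             "background_with": res.background_with, "background_without": res.background_without,
             "er": res.er, "ci_low": res.ci_low, "ci_high": res.ci_high,
             "p_value": res.test.p_value, "direction": res.test.direction}
        )
    io.write_table(pd.DataFrame(rows), outdir / "enrichment.tsv", index=False)
    manifest["counts"]["elements_skipped_unknown_chrom"] = int(mapping.n_skipped_elements)


def _stage_call(config, classification, outdir, manifest):
    cohort = io.read_matrix(config.inputs["cohort"])
    thr = config.thresholds
    calls, flags = ctcall.call_cohort(
        cohort, classification, config.cancer_type,
        protein_classes=classification["protein_class"],
        expression_threshold=thr.expression,
        ee_params=ctcall.EEParams(thr.ee_floor, thr.ee_k),
        fraction_threshold=thr.fraction,
    )
    io.write_table(calls, outdir / "ct_calls.tsv")
    io.write_matrix(flags.astype(int), outdir / "ee_flags.tsv")
    manifest["counts"]["ct_genes"] = int(calls["is_ct"].sum())
    manifest["counts"]["eectg"] = int(calls["is_eectg"].sum())
    manifest["counts"]["eectp"] = int(calls["is_eectp"].sum())
    return calls, flags


def _eectp_activated(calls, flags) -> tuple[list, pd.Series]:
    eectps = sorted(calls.index[calls["is_eectp"]])
    activated = ctcall.activated_counts(flags, eectps)
    return eectps, activated


def _stage_mutassoc(config, calls, flags, outdir, manifest) -> None:
    maf = io.read_maf(config.inputs["maf"])
    smgs = [l.strip() for l in Path(config.inputs["smg_list"]).read_text().splitlines() if l.strip()]
    samples = list(flags.columns)
    eectps, activated = _eectp_activated(calls, flags)
    ratios = mutassoc.mutation_ratios(maf, samples, set(smgs), set(config.exclude_genes),
                                      nonsilent_only=config.nonsilent_only)
    manifest["counts"]["samples_without_mutations"] = int(ratios.isna().sum())

    res = mutassoc.ratio_vs_activation(ratios, activated)
    io.write_table(
        pd.DataFrame(
            [{"unit": res.unit, "beta": res.effect, "p_value": res.test.p_value,
              "test": res.test.test_name, "direction": res.test.direction,
              "n_used": res.n_used}]
        ),
        outdir / "mut_assoc_cohort.tsv", index=False,
    )
    mut_status = mutassoc.mutation_status(maf, samples, smgs,
                                          nonsilent_only=config.nonsilent_only)
    ee_sub = flags.loc[[g for g in eectps if g in flags.index]]
    smg_df, pair_df = mutassoc.gene_level_tests(mut_status, ee_sub, activated)
    io.write_table(smg_df, outdir / "mut_assoc_smg.tsv")
    io.write_table(pair_df, outdir / "mut_assoc_pairs.tsv", index=False)


def _stage_methassoc(config, calls, flags, outdir, manifest) -> None:
    meth = io.read_matrix(config.inputs["methylation"])
    eectps, activated = _eectp_activated(calls, flags)
    present = [g for g in eectps if g in meth.index]
    if not present:
        manifest["stages_skipped"]["meth-assoc"] = "no EECTP with methylation data"
        return
    mean_beta, n_missing = methassoc.mean_promoter_beta(meth, present)
    gw_mean, _ = methassoc.mean_promoter_beta(meth, list(meth.index))
    res = methassoc.methylation_vs_activation(mean_beta, activated, genomewide_mean=gw_mean)
    io.write_table(
        pd.DataFrame(
            [{"unit": res.unit, "beta": res.effect, "p_value": res.test.p_value,
              "test": res.test.test_name, "direction": res.test.direction,
              "n_used": res.n_used}]
        ),
        outdir / "meth_assoc_cohort.tsv", index=False,
    )
    per_gene = methassoc.per_gene_methylation_tests(meth, flags, eectps)
    io.write_table(per_gene, outdir / "meth_assoc_genes.tsv")
    manifest["counts"]["eectp_without_methylation"] = int(len(eectps) - len(present))


def _stage_cna(config, calls, flags, outdir, manifest) -> None:
    seg = io.read_seg(config.inputs["seg"])
    aseg = io.read_allele_seg(config.inputs["allele_seg"])
    genome_length = int(
        max(seg.groupby("chrom")["end"].max().sum(), aseg.groupby("chrom")["end"].max().sum())
    )
    thr = config.thresholds
    burdens = cna.burden_table(seg, thr.gain_cut, thr.loss_cut)
    scores = cna.score_table(aseg, genome_length)
    table = scores.join(burdens, how="outer")
    io.write_table(table, outdir / "cna_scores.tsv")

    if calls is None or flags is None:
        return
    target = config.cna_target_gene
    if target is None:
        eectgs = calls[calls["is_eectg"]]
        if len(eectgs) == 0:
            manifest["counts"]["cna_association_target"] = "none"
            return
        target = eectgs["ee_fraction"].sort_values(ascending=False).index[0]
    cohort = io.read_matrix(config.inputs["cohort"]) if _have(config, "cohort") else None
    rows = []
    if cohort is not None and target in cohort.index:
        shared = [s for s in cohort.columns if s in burdens.index]
        res = cna.activation_vs_instability(
            burdens.reindex(shared), cohort.loc[target, shared], kind="expression"
        )
        rows.append({"target_gene": target, "measure": "focal_burden_vs_expression",
                     "effect": res.effect, "p_value": res.test.p_value,
                     "direction": res.test.direction, "n_used": res.n_used})
    if target in flags.index:
        shared = [s for s in flags.columns if s in scores.index]
        res = cna.activation_vs_instability(
            scores.loc[shared, "s_ai"], flags.loc[target, shared], kind="ee"
        )
        rows.append({"target_gene": target, "measure": "s_ai_ee_vs_non_ee",
                     "effect": res.effect, "p_value": res.test.p_value,
                     "direction": res.test.direction, "n_used": res.n_used})
    io.write_table(pd.DataFrame(rows), outdir / "cna_assoc.tsv", index=False)
    manifest["counts"]["cna_association_target"] = str(target)


def _stage_ncrna(config, annotation, classification, calls, outdir, manifest) -> None:
    cohort = io.read_matrix(config.inputs["cohort"])
    thr = config.thresholds
    ct_coding = sorted(calls.index[calls["is_ct"]])
    ct_nc = ncrna.call_ct_ncrnas(
        cohort, classification, thr.expression, thr.fraction
    )
    pairs = ncrna.pair_genes(ct_coding, ct_nc, annotation.genes, thr.max_pair_distance)
    manifest["counts"]["ct_ncrnas"] = len(ct_nc)
    manifest["counts"]["ncrna_pairs"] = int(len(pairs))
    if len(pairs) == 0:
        io.write_table(pairs, outdir / "ncrna_pairs.tsv", index=False)
        return
    corr = ncrna.correlate_pairs(pairs, cohort,
                                 pd.Series(config.cancer_type, index=cohort.columns))
    io.write_table(corr, outdir / "ncrna_pairs.tsv", index=False)
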