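"""Seeded synthetic data emulating the statistical structure of a
multi-panel cancer-testis study.

The generator produces every input the pipeline consumes — a gene
annotation with transcripts, a testis-specific regulatory-element
track, three normal-tissue expression panels (a large GTEx-style panel,
a medium HBM-style panel, a small NJMU-style panel, each containing a
tissue labelled ``testis``), a proteome peptide table, and a tumour
cohort with expression, somatic mutations, promoter methylation and
copy-number segment tables — together with the planted ground truth, so
that downstream recovery is checkable.

Planted structure:

* testis-specific genes (TSGs) expressed only in testis, plus optional
  low-level leak noise in other tissues;
* genes that are broadly expressed at the gene level but carry one
  testis-specific transcript (the C6a pattern);
* proteins whose only testis evidence comes through shared peptides;
* a subset of coding TSGs reactivated in the tumour cohort: rare
  extreme-expression (EE) activation at a configurable per-gene
  frequency, with magnitudes far above the calling threshold;
* a designated significantly-mutated gene whose mutations avoid
  EE-activated samples (mutual exclusivity, tunable strength);
* a negative coupling between each sample's SMG mutation ratio and its
  number of activated genes (tunable slope);
* promoter hypomethylation of activated genes in activated samples;
* allele-imbalanced copy-number segments enriched in samples where the
  designated imbalance-driver gene is activated;
* CT-ncRNA partners adjacent (< 100 kb) to activated coding genes, one
  co-activated and one repressive.

Every output table draws from its own RNG stream split from the master
seed, so regenerating one table never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "Annotation",
    "NormalPanels",
    "TumorBundle",
    "GroundTruth",
    "generate_reference",
    "generate_normal_panels",
    "generate_tumor_cohort",
]

ELEMENT_KINDS = ("promoter", "methylation_site", "ncRNA", "enhancer")
ELEMENT_WIDTHS = {"promoter": 200, "methylation_site": 100, "ncRNA": 500, "enhancer": 400}
VARIANT_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Silent", "Splice_Site")

HBM_N_TISSUES = 16
NJMU_N_TISSUES = 5
PROTEOME_N_TISSUES = 16


class ConfigurationError(ValueError):
    """Invalid simulation configuration; names the offending field."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_tissues: int = 27
    n_genes: int = 1000
    n_planted_tsg: int = 60
    n_planted_ee_genes: int = 8
    cohort_size: int = 300
    ee_frequency: float = 0.05
    exclusivity_strength: float = 1.0
    methylation_effect: float = 0.3
    genome_length: int = 300_000_000
    n_chromosomes: int = 5
    noise_model: str = "lognormal"
    dispersion: float = 0.5
    leak_level: float = 1.0
    coding_fraction: float = 0.7
    element_background_rate: float = 0.05
    element_enrichment: float = 10.0
    n_planted_c6a: int = 5
    n_shared_only_proteins: int = 3
    n_ct_ncrna_pairs: int = 2
    smg_mutation_rate: float = 0.2
    n_carrier_smgs: int = 3
    passenger_mut_mean: float = 40.0
    mutation_activation_slope: float = -5.0
    mutation_ratio_low: float = 0.02
    mutation_ratio_high: float = 0.2
    testis_mean: float = 50.0
    background_mean: float = 20.0
    tumor_background_mean: float = 100.0
    ee_magnitude_low: float = 10.0
    ee_magnitude_high: float = 100.0
    ee_floor: float = 32.0
    peptide_coverage: float = 0.8
    cancer_type: str = "SYNTH"

    def validate(self) -> None:
        def _check(cond, fieldname, msg):
            if not cond:
                raise ConfigurationError(fieldname, msg)

        _check(self.n_genes > 0, "n_genes", "must be positive")
        _check(0 <= self.n_planted_tsg <= self.n_genes, "n_planted_tsg",
               "must lie in [0, n_genes]")
        _check(
            self.n_planted_tsg >= self.n_planted_ee_genes + self.n_ct_ncrna_pairs,
            "n_planted_tsg",
            "must cover planted EE genes and CT-ncRNA partners",
        )
        _check(0 <= self.n_planted_ee_genes, "n_planted_ee_genes", "must be >= 0")
        _check(self.n_ct_ncrna_pairs <= self.n_planted_ee_genes, "n_ct_ncrna_pairs",
               "needs one planted EE gene per pair")
        _check(0.0 <= self.ee_frequency <= 1.0, "ee_frequency", "must lie in [0, 1]")
        _check(0.0 <= self.exclusivity_strength <= 1.0, "exclusivity_strength",
               "must lie in [0, 1]")
        _check(0.0 <= self.methylation_effect <= 1.0, "methylation_effect",
               "must lie in [0, 1]")
        _check(self.genome_length > 0, "genome_length", "must be positive")
        _check(self.n_chromosomes > 0, "n_chromosomes", "must be positive")
        _check(self.n_tissues >= 2, "n_tissues", "need testis plus at least one other")
        _check(self.noise_model in ("lognormal",), "noise_model",
               "only 'lognormal' is implemented")
        _check(self.dispersion >= 0, "dispersion", "must be >= 0")
        _check(self.leak_level >= 0, "leak_level", "must be >= 0")
        _check(0 < self.coding_fraction <= 1, "coding_fraction", "must lie in (0, 1]")
        _check(self.element_background_rate > 0, "element_background_rate",
               "must be positive")
        _check(self.element_enrichment > 0, "element_enrichment", "must be positive")
        _check(0 <= self.mutation_ratio_low <= self.mutation_ratio_high <= 1,
               "mutation_ratio_low", "need 0 <= low <= high <= 1")
        _check(0 < self.smg_mutation_rate < 1, "smg_mutation_rate",
               "must lie in (0, 1)")

    def stream(self, name: str) -> np.random.Generator:
        """Named RNG stream split deterministically from the master seed."""
        order = (
            "annotation", "elements", "panel_gtex", "panel_hbm", "panel_njmu",
            "transcripts", "transcript_panel", "peptides", "tumor_expression",
            "activation", "mutations", "methylation", "segments_logratio",
            "segments_allele",
        )
        if name not in order:
            raise KeyError(name)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(order.index(name),))
        return np.random.default_rng(ss)


@dataclass
class Annotation:
    """Synthetic gene annotation; planted roles travel as flag columns."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, biotype, flags
    transcripts: pd.DataFrame  # transcript_id, gene_id, chrom, start, end, strand, testis_specific
    chrom_lengths: dict

    def planted(self, flag: str) -> list[str]:
        return self.genes.loc[self.genes[flag], "gene_id"].tolist()


@dataclass
class NormalPanels:
    panels: dict  # {"gtex"|"hbm"|"njmu": genes x tissues DataFrame}
    transcript_panel: pd.DataFrame  # transcripts x gtex tissues
    transcript_gene_map: pd.Series
    peptides: pd.DataFrame  # peptide_id, protein_ids, tissue columns
    proteome_tissues: list


@dataclass
class GroundTruth:
    tsg_gene_ids: set
    ee_gene_ids: set
    activation: pd.DataFrame  # EE genes x samples, bool
    exclusive_mutation_gene: str
    smg_genes: list
    hypomethylated_gene_ids: set
    imbalance_driver_gene: str
    ncrna_pairs: list  # [(coding_gene, ncrna_gene, "positive"|"repressive")]
    c6a_gene_ids: set
    shared_only_proteins: set


@dataclass
class TumorBundle:
    cancer_type: str
    expression: pd.DataFrame  # genes x samples
    mutations: pd.DataFrame  # MAF-like
    methylation: pd.DataFrame  # genes x samples betas
    segments_logratio: pd.DataFrame
    segments_allele: pd.DataFrame
    truth: GroundTruth


def _chrom_lengths(config: SimulationConfig) -> dict:
    base = config.genome_length // config.n_chromosomes
    lengths = {}
    for i in range(config.n_chromosomes):
        extra = config.genome_length % config.n_chromosomes if i == 0 else 0
        lengths[f"chr{i + 1}"] = base + extra
    return lengths


def generate_reference(config: SimulationConfig):
    """Generate the gene annotation and the testis-specific element track.

    Returns ``(Annotation, elements DataFrame)``.  Planted TSGs, EE
    genes, CT-ncRNA partners and C6a genes are marked by boolean columns
    on the annotation.  Elements are placed inside each gene's
    assignment window, with planted TSGs receiving elements at
    ``element_enrichment`` times the background rate.
    """
    config.validate()
    rng = config.stream("annotation")
    n = config.n_genes
    per_chrom = math.ceil(n / config.n_chromosomes)
    chrom_lengths = _chrom_lengths(config)
    chrom_names = list(chrom_lengths)

    # --- select planted roles over placement indices -------------------
    n_ee = config.n_planted_ee_genes
    n_pairs = config.n_ct_ncrna_pairs
    ee_idx: list[int] = []
    taken = set()
    candidates = list(range(n - 1))
    rng.shuffle(candidates)
    for i in candidates:
        if len(ee_idx) == n_ee:
            break
        # keep the following slot free for a possible ncRNA partner on the
        # same chromosome, and keep EE genes apart from each other
        if i % per_chrom == per_chrom - 1:
            continue
        if any(abs(i - j) < 3 for j in ee_idx):
            continue
        ee_idx.append(i)
    if len(ee_idx) < n_ee:
        raise ConfigurationError("n_planted_ee_genes", "gene universe too small to place")
    ee_idx.sort()
    pair_nc_idx = [i + 1 for i in ee_idx[:n_pairs]]
    taken.update(ee_idx)
    taken.update(pair_nc_idx)

    remaining = [i for i in range(n) if i not in taken]
    rng.shuffle(remaining)
    n_more_tsg = config.n_planted_tsg - n_ee - n_pairs
    tsg_extra = sorted(remaining[:n_more_tsg])
    taken.update(tsg_extra)

    biotype = np.empty(n, dtype=object)
    rand_bio = rng.random(n)
    for i in range(n):
        biotype[i] = "coding" if rand_bio[i] < config.coding_fraction else "noncoding"
    for i in ee_idx:
        biotype[i] = "coding"
    for i in pair_nc_idx:
        biotype[i] = "noncoding"

    non_planted_coding = [i for i in range(n) if i not in taken and biotype[i] == "coding"]
    rng.shuffle(non_planted_coding)
    c6a_idx = sorted(non_planted_coding[: config.n_planted_c6a])

    is_tsg = np.zeros(n, dtype=bool)
    is_tsg[list(ee_idx) + pair_nc_idx + tsg_extra] = True
    is_ee = np.zeros(n, dtype=bool)
    is_ee[ee_idx] = True
    is_pair_nc = np.zeros(n, dtype=bool)
    is_pair_nc[pair_nc_idx] = True
    is_c6a = np.zeros(n, dtype=bool)
    is_c6a[c6a_idx] = True

    # --- place genes ---------------------------------------------------
    rows = []
    for i in range(n):
        chrom_i = i // per_chrom
        chrom = chrom_names[chrom_i]
        if i % per_chrom == 0:
            cursor = int(rng.integers(10_000, 50_000))
        length = int(rng.integers(2_000, 20_001))
        gap = int(rng.integers(5_000, 50_001))
        start = cursor
        end = start + length
        if end >= chrom_lengths[chrom]:
            raise ConfigurationError(
                "genome_length", "too short for the requested gene universe"
            )
        cursor = end + gap
        rows.append(
            {
                "gene_id": f"G{i:05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "biotype": biotype[i],
                "is_planted_tsg": bool(is_tsg[i]),
                "is_planted_ee": bool(is_ee[i]),
                "is_pair_ncrna": bool(is_pair_nc[i]),
                "is_planted_c6a": bool(is_c6a[i]),
            }
        )
    genes = pd.DataFrame(rows)

    # --- transcripts ----------------------------------------------------
    trng = config.stream("transcripts")
    trows = []
    for row in genes.itertuples():
        n_tx = int(trng.integers(1, 4))
        if row.is_planted_c6a:
            n_tx = max(n_tx, 2)
        glen = row.end - row.start
        for t in range(n_tx):
            off = int(trng.integers(0, max(1, glen // 4)))
            tlen = int(trng.integers(glen // 2, glen + 1))
            tstart = row.start + off
            tend = min(row.end, tstart + tlen)
            trows.append(
                {
                    "transcript_id": f"{row.gene_id}.t{t}",
                    "gene_id": row.gene_id,
                    "chrom": row.chrom,
                    "start": tstart,
                    "end": max(tend, tstart + 1),
                    "strand": row.strand,
                    # first transcript of a C6a gene carries the
                    # testis-restricted pattern
                    "testis_specific": bool(row.is_planted_tsg or (row.is_planted_c6a and t == 0)),
                }
            )
    transcripts = pd.DataFrame(trows)
    annotation = Annotation(genes, transcripts, chrom_lengths)

    # --- regulatory elements --------------------------------------------
    erng = config.stream("elements")
    erows = []
    counter = 0
    for kind in ELEMENT_KINDS:
        width = ELEMENT_WIDTHS[kind]
        for row in genes.itertuples():
            p = config.element_background_rate * (
                config.element_enrichment if row.is_planted_tsg else 1.0
            )
            if erng.random() >= min(p, 1.0):
                continue
            if kind in ("promoter", "methylation_site"):
                tss = row.start if row.strand == "+" else row.end
                lo = tss - 1000 if row.strand == "+" else tss - 100
                hi = (tss + 100 if row.strand == "+" else tss + 1000) - width
            else:
                lo, hi = row.start - 50_000, row.end + 50_000 - width
            lo = max(lo, 0)
            hi = max(hi, lo + 1)
            start = int(erng.integers(lo, hi))
            end = min(start + width, chrom_lengths[row.chrom] - 1)
            erows.append(
                {
                    "element_id": f"E{counter:06d}",
                    "kind": kind,
                    "chrom": row.chrom,
                    "start": start,
                    "end": end,
                    "testis_specific": True,
                }
            )
            counter += 1
    elements = pd.DataFrame(
        erows, columns=["element_id", "kind", "chrom", "start", "end", "testis_specific"]
    )
    return annotation, elements


def _panel_tissues(config: SimulationConfig) -> dict:
    return {
        "gtex": ["testis"] + [f"gtex_t{i:02d}" for i in range(1, config.n_tissues)],
        "hbm": ["testis"] + [f"hbm_t{i:02d}" for i in range(1, HBM_N_TISSUES)],
        "njmu": ["testis"] + [f"njmu_t{i:02d}" for i in range(1, NJMU_N_TISSUES)],
    }


def _panel_matrix(config, annotation, tissues, rng) -> pd.DataFrame:
    """One normal-tissue gene x tissue panel."""
    genes = annotation.genes
    n_t = len(tissues)
    testis_col = tissues.index("testis")
    mat = np.zeros((len(genes), n_t))
    for gi, row in enumerate(genes.itertuples()):
        if row.is_planted_tsg:
            testis = config.testis_mean * rng.lognormal(0.0, config.dispersion)
            leak = np.abs(rng.normal(0.0, config.leak_level, size=n_t)) if config.leak_level > 0 else np.zeros(n_t)
            vals = leak
            vals[testis_col] = testis
        else:
            base = config.background_mean * rng.lognormal(0.0, 0.5)
            vals = base * rng.lognormal(0.0, config.dispersion, size=n_t)
        mat[gi] = vals
    return pd.DataFrame(mat, index=genes["gene_id"].to_numpy(), columns=tissues)


def generate_normal_panels(config: SimulationConfig, annotation: Annotation) -> NormalPanels:
    """Three normal-tissue panels, a transcript panel and a peptide table."""
    config.validate()
    tissues = _panel_tissues(config)
    genes = annotation.genes

    panels = {}
    for key in ("gtex", "hbm", "njmu"):
        panels[key] = _panel_matrix(config, annotation, tissues[key], config.stream(f"panel_{key}"))

    # Transcript-level panel for the reference (GTEx-style) tissue set.
    # The gene-level panel is replaced by the transcript sum so that the
    # two levels are consistent.
    trng = config.stream("transcript_panel")
    gtex_tissues = tissues["gtex"]
    n_t = len(gtex_tissues)
    testis_col = gtex_tissues.index("testis")
    tx = annotation.transcripts
    tmat = np.zeros((len(tx), n_t))
    for ti, row in enumerate(tx.itertuples()):
        if row.testis_specific:
            vals = (np.abs(trng.normal(0.0, config.leak_level, size=n_t))
                    if config.leak_level > 0 else np.zeros(n_t))
            vals[testis_col] = config.testis_mean * trng.lognormal(0.0, config.dispersion)
        else:
            base = config.background_mean * trng.lognormal(0.0, 0.5)
            vals = base * trng.lognormal(0.0, config.dispersion, size=n_t)
        tmat[ti] = vals
    transcript_panel = pd.DataFrame(tmat, index=tx["transcript_id"].to_numpy(),
                                    columns=gtex_tissues)
    tx_gene_map = pd.Series(tx["gene_id"].to_numpy(), index=tx["transcript_id"].to_numpy())

    gene_from_tx = transcript_panel.groupby(tx_gene_map).sum()
    panels["gtex"] = gene_from_tx.reindex(genes["gene_id"].to_numpy())

    peptides = _peptide_table(config, annotation)
    return NormalPanels(panels, transcript_panel, tx_gene_map, peptides,
                        _proteome_tissues())


def _proteome_tissues() -> list:
    return ["testis"] + [f"hpm_t{i:02d}" for i in range(1, PROTEOME_N_TISSUES)]


def _peptide_table(config: SimulationConfig, annotation: Annotation) -> pd.DataFrame:
    rng = config.stream("peptides")
    tissues = _proteome_tissues()
    n_t = len(tissues)
    genes = annotation.genes
    coding = genes[genes["biotype"] == "coding"]

    planted_coding = coding[coding["is_planted_tsg"]]["gene_id"].tolist()
    background_coding = coding[~coding["is_planted_tsg"]]["gene_id"].tolist()
    shared_only = (
        background_coding[: config.n_shared_only_proteins] if planted_coding else []
    )
    partners = (planted_coding * (len(shared_only) + 1)) if planted_coding else []

    rows = []
    counter = 0

    def _pep_values(testis_specific: bool) -> np.ndarray:
        if testis_specific:
            vals = (np.abs(rng.normal(0.0, 0.2 * config.leak_level, size=n_t))
                    if config.leak_level > 0 else np.zeros(n_t))
            vals[0] = 30.0 * rng.lognormal(0.0, 0.3)
        else:
            vals = 10.0 * rng.lognormal(0.0, 0.4, size=n_t)
        return vals

    for gid in coding["gene_id"]:
        if gid in shared_only:
            continue  # gets shared peptides only, below
        planted = gid in set(planted_coding)
        if not planted and rng.random() > config.peptide_coverage:
            continue  # protein with no peptide evidence -> no_data
        for _ in range(int(rng.integers(2, 5))):
            vals = _pep_values(planted)
            rows.append([f"P{counter:06d}", gid, *vals])
            counter += 1

    for i, gid in enumerate(shared_only):
        partner = partners[i]
        for _ in range(2):
            vals = _pep_values(True)  # testis evidence via the shared peptide
            rows.append([f"P{counter:06d}", f"{gid};{partner}", *vals])
            counter += 1

    return pd.DataFrame(rows, columns=["peptide_id", "protein_ids", *tissues])


def generate_tumor_cohort(config: SimulationConfig, annotation: Annotation) -> TumorBundle:
    """Tumour cohort with expression, mutations, methylation and segments."""
    config.validate()
    if config.cohort_size < 2:
        raise ConfigurationError("cohort_size", "must be at least 2")
    genes = annotation.genes
    gene_ids = genes["gene_id"].to_numpy()
    n_s = config.cohort_size
    samples = [f"S{i:04d}" for i in range(n_s)]

    ee_genes = annotation.planted("is_planted_ee")
    pair_ncrnas = annotation.planted("is_pair_ncrna")
    tsg_all = annotation.planted("is_planted_tsg")
    n_ee = len(ee_genes)

    background_coding = genes[
        (genes["biotype"] == "coding") & ~genes["is_planted_tsg"] & ~genes["is_planted_c6a"]
    ]["gene_id"].tolist()
    # the first few background coding genes are reserved for shared-only
    # peptide planting; SMGs start after them
    offset = config.n_shared_only_proteins
    if len(background_coding) < offset + 1 + config.n_carrier_smgs + 5:
        raise ConfigurationError("n_genes", "too few background coding genes for SMGs")
    exclusive_smg = background_coding[offset]
    carrier_smgs = background_coding[offset + 1 : offset + 1 + config.n_carrier_smgs]
    passenger_pool = background_coding[offset + 1 + config.n_carrier_smgs :]

    # --- per-sample mutation-ratio targets and activation ----------------
    arng = config.stream("activation")
    ratio_target = arng.uniform(config.mutation_ratio_low, config.mutation_ratio_high, n_s)
    mean_r = (config.mutation_ratio_low + config.mutation_ratio_high) / 2.0
    slope = config.mutation_activation_slope
    alpha = n_ee * config.ee_frequency - slope * mean_r
    p_sample = np.clip(alpha + slope * ratio_target, 0.0, max(n_ee, 1)) / max(n_ee, 1)
    activation = pd.DataFrame(
        arng.random((n_ee, n_s)) < p_sample[None, :], index=ee_genes, columns=samples
    )

    # --- expression -------------------------------------------------------
    xrng = config.stream("tumor_expression")
    expr = np.zeros((len(gene_ids), n_s))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    planted_set = set(tsg_all)
    ee_set = set(ee_genes)
    pair_info = []
    pair_nc_set = set(pair_ncrnas)

    for gi, row in enumerate(genes.itertuples()):
        gid = row.gene_id
        if gid in ee_set:
            base = xrng.uniform(0.0, 3.0, size=n_s)
            act = activation.loc[gid].to_numpy()
            magnitude = config.ee_floor * xrng.uniform(
                config.ee_magnitude_low, config.ee_magnitude_high, size=n_s
            )
            expr[gi] = np.where(act, magnitude, base)
        elif gid in pair_nc_set:
            continue  # filled below from the partner
        elif gid in planted_set:
            # CT-silent TSG: essentially unexpressed in tumours
            expr[gi] = np.where(xrng.random(n_s) < 0.2, xrng.uniform(0.0, 1.0, n_s), 0.0)
        else:
            expr[gi] = config.tumor_background_mean * xrng.lognormal(
                0.0, config.dispersion, size=n_s
            )

    for k, nc_gid in enumerate(pair_ncrnas):
        partner = ee_genes[k]
        act = activation.loc[partner].to_numpy()
        sign = "positive" if k % 2 == 0 else "repressive"
        coding_expr = expr[gene_pos[partner]]
        if sign == "positive":
            # cis-coactivated: tracks the partner dose-dependently
            vals = 0.5 * coding_expr * xrng.lognormal(0.0, 0.3, n_s)
        else:
            # repressor: high when the partner is silent, dose-dependently
            # squelched as the partner comes up
            vals = 50.0 * xrng.lognormal(0.0, 0.3, n_s) / (1.0 + coding_expr)
        expr[gene_pos[nc_gid]] = vals
        pair_info.append((partner, nc_gid, sign))

    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)

    # --- mutations --------------------------------------------------------
    mrng = config.stream("mutations")
    maf_rows = []
    passenger_counts = mrng.poisson(config.passenger_mut_mean, size=n_s)
    for si, s in enumerate(samples):
        n_pass = int(passenger_counts[si])
        r = ratio_target[si]
        n_smg = int(round(n_pass * r / (1.0 - r))) if r < 1 else n_pass
        for g in mrng.choice(passenger_pool, size=n_pass, replace=True):
            maf_rows.append((g, s, VARIANT_CLASSES[int(mrng.integers(0, len(VARIANT_CLASSES)))]))
        if carrier_smgs:
            for g in mrng.choice(carrier_smgs, size=n_smg, replace=True):
                maf_rows.append((g, s, VARIANT_CLASSES[int(mrng.integers(0, len(VARIANT_CLASSES)))]))

    # exclusive SMG: weighted sampling without replacement that avoids
    # samples where the first planted EE gene is activated
    n_mut = int(round(config.smg_mutation_rate * n_s))
    if n_ee:
        act0 = activation.loc[ee_genes[0]].to_numpy()
    else:
        act0 = np.zeros(n_s, dtype=bool)
    weights = np.where(act0, 1.0 - config.exclusivity_strength, 1.0)
    u = mrng.random(n_s)
    with np.errstate(divide="ignore"):
        keys = np.where(weights > 0, u ** (1.0 / np.where(weights > 0, weights, 1.0)), -1.0)
    mutated_idx = np.argsort(keys)[::-1][:n_mut]
    for si in sorted(mutated_idx):
        maf_rows.append((exclusive_smg, samples[si], "Missense_Mutation"))

    mutations = pd.DataFrame(
        maf_rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    ).sort_values(["Tumor_Sample_Barcode", "Hugo_Symbol"], kind="stable").reset_index(drop=True)

    # --- methylation ------------------------------------------------------
    hrng = config.stream("methylation")
    betas = np.clip(hrng.normal(0.5, 0.1, size=(len(gene_ids), n_s)), 0, 1)
    for gid in ee_genes:
        base = hrng.normal(0.7, 0.05, size=n_s)
        act = activation.loc[gid].to_numpy()
        betas[gene_pos[gid]] = np.clip(base - config.methylation_effect * act, 0, 1)
    methylation = pd.DataFrame(betas, index=gene_ids, columns=samples)

    # --- copy-number segments --------------------------------------------
    driver = ee_genes[1] if n_ee > 1 else (ee_genes[0] if n_ee else "")
    driver_act = (activation.loc[driver].to_numpy() if driver else np.zeros(n_s, dtype=bool))

    lrng = config.stream("segments_logratio")
    seg_rows = []
    for si, s in enumerate(samples):
        p_aber = 0.05 + (0.45 if driver_act[si] else 0.0)
        for chrom, clen in annotation.chrom_lengths.items():
            cuts = np.sort(lrng.integers(1, clen, size=5))
            bounds = [0, *cuts.tolist(), clen]
            for b0, b1 in zip(bounds[:-1], bounds[1:]):
                if b1 <= b0:
                    continue
                if lrng.random() < p_aber:
                    cn = float(lrng.uniform(0.3, 1.0) * (1 if lrng.random() < 0.5 else -1))
                else:
                    cn = float(lrng.normal(0.0, 0.02))
                seg_rows.append((s, chrom, int(b0), int(b1), round(cn, 4)))
    segments_logratio = pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "seg_cn"]
    )

    srng = config.stream("segments_allele")
    aseg_rows = []
    for si, s in enumerate(samples):
        q = 0.05 + (0.25 if driver_act[si] else 0.0)
        for chrom, clen in annotation.chrom_lengths.items():
            cuts = np.sort(srng.integers(1, clen, size=5))
            bounds = [0, *cuts.tolist(), clen]
            for b0, b1 in zip(bounds[:-1], bounds[1:]):
                if b1 <= b0:
                    continue
                if srng.random() < q:
                    r = srng.random()
                    if r < 0.4:
                        nA, nB = 2, 1  # AiCNA
                    elif r < 0.8:
                        nA, nB = 2, 0  # CnLOH
                    else:
                        nA, nB = 2, 2  # AbCNA
                else:
                    nA, nB = 1, 1
                aseg_rows.append((s, chrom, int(b0), int(b1), nA, nB))
    segments_allele = pd.DataFrame(
        aseg_rows, columns=["sample_id", "chrom", "start", "end", "nA", "nB"]
    )

    truth = GroundTruth(
        tsg_gene_ids=set(tsg_all),
        ee_gene_ids=set(ee_genes),
        activation=activation,
        exclusive_mutation_gene=exclusive_smg,
        smg_genes=[exclusive_smg, *carrier_smgs],
        hypomethylated_gene_ids=set(ee_genes),
        imbalance_driver_gene=driver,
        ncrna_pairs=pair_info,
        c6a_gene_ids=set(annotation.planted("is_planted_c6a")),
        shared_only_proteins=set(
            _peptide_shared_only(config, annotation)
        ),
    )
    return TumorBundle(
        config.cancer_type, expression, mutations, methylation,
        segments_logratio, segments_allele, truth,
    )


def _peptide_shared_only(config: SimulationConfig, annotation: Annotation) -> list:
    coding = annotation.genes[annotation.genes["biotype"] == "coding"]
    if not coding["is_planted_tsg"].any():
        return []
    background = coding[~coding["is_planted_tsg"]]["gene_id"].tolist()
    return background[: config.n_shared_only_proteins]
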