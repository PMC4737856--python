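"""Generator contracts: determinism, value ranges, planted structure."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ctcaller import synthdata as sd

from _oracles import binom_interval_99


def _tiny(seed=0, **kw):
    defaults = dict(seed=seed, n_genes=80, n_planted_tsg=14, n_planted_ee_genes=4,
                    n_ct_ncrna_pairs=1, n_planted_c6a=2, cohort_size=60,
                    n_chromosomes=3, genome_length=30_000_000)
    defaults.update(kw)
    return sd.SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw,fieldname",
        [
            ({"ee_frequency": 1.5}, "ee_frequency"),
            ({"genome_length": 0}, "genome_length"),
            ({"n_planted_tsg": 200}, "n_planted_tsg"),
            ({"exclusivity_strength": -0.1}, "exclusivity_strength"),
            ({"noise_model": "gamma"}, "noise_model"),
        ],
    )
    def test_invalid_field_named_in_error(self, kw, fieldname):
        cfg = _tiny(**kw)
        with pytest.raises(sd.ConfigurationError) as err:
            cfg.validate()
        assert err.value.fieldname == fieldname

    def test_cohort_too_small(self):
        cfg = _tiny(cohort_size=1)
        ann, _ = sd.generate_reference(cfg)
        with pytest.raises(sd.ConfigurationError):
            sd.generate_tumor_cohort(cfg, ann)


class TestDeterminism:
    def test_reference_identical_across_runs(self):
        a1, e1 = sd.generate_reference(_tiny(3))
        a2, e2 = sd.generate_reference(_tiny(3))
        assert a1.genes.equals(a2.genes)
        assert a1.transcripts.equals(a2.transcripts)
        assert e1.equals(e2)

    def test_different_seeds_differ(self):
        a1, _ = sd.generate_reference(_tiny(3))
        a2, _ = sd.generate_reference(_tiny(4))
        assert not a1.genes.equals(a2.genes)

    def test_tumor_bundle_identical_across_runs(self):
        cfg = _tiny(5)
        ann, _ = sd.generate_reference(cfg)
        t1 = sd.generate_tumor_cohort(cfg, ann)
        t2 = sd.generate_tumor_cohort(cfg, ann)
        assert t1.expression.equals(t2.expression)
        assert t1.mutations.equals(t2.mutations)
        assert t1.methylation.equals(t2.methylation)
        assert t1.segments_allele.equals(t2.segments_allele)

    def test_written_bundle_byte_identical(self, tmp_path):
        from ctcaller.pipeline import PipelineConfig, run_pipeline

        digests = []
        for sub in ("a", "b"):
            cfg = PipelineConfig(outdir=str(tmp_path / sub), seed=9,
                                 simulate=dict(n_genes=80, n_planted_tsg=14,
                                               n_planted_ee_genes=4, n_ct_ncrna_pairs=1,
                                               n_planted_c6a=2, cohort_size=60,
                                               n_chromosomes=3, genome_length=30_000_000))
            run_pipeline(cfg, stages=["simulate"])
            import hashlib

            d = {}
            for f in sorted((tmp_path / sub / "inputs").iterdir()):
                d[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
            digests.append(d)
        assert digests[0] == digests[1]


class TestGeneratedInvariants:
    def test_annotation_geometry(self, annotation):
        g = annotation.genes
        assert (g["start"] < g["end"]).all()
        assert g["strand"].isin(["+", "-"]).all()
        for chrom, grp in g.groupby("chrom"):
            s = grp.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()
            assert s["end"].max() < annotation.chrom_lengths[chrom]

    def test_abundances_non_negative(self, panels):
        for key, mat in panels.panels.items():
            assert (mat.to_numpy() >= 0).all(), key

    def test_betas_in_unit_interval(self, tumor):
        b = tumor.methylation.to_numpy()
        assert b.min() >= 0 and b.max() <= 1

    def test_segments_non_overlapping_and_in_range(self, tumor, annotation):
        for table in (tumor.segments_logratio, tumor.segments_allele):
            assert (table["start"] < table["end"]).all()
            for (s, chrom), grp in table.groupby(["sample_id", "chrom"]):
                g = grp.sort_values("start")
                assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()
                assert g["end"].max() <= annotation.chrom_lengths[chrom]

    def test_ground_truth_ids_exist(self, tumor, annotation):
        universe = set(annotation.genes["gene_id"])
        t = tumor.truth
        for ids in (t.tsg_gene_ids, t.ee_gene_ids, t.hypomethylated_gene_ids,
                    t.c6a_gene_ids, set(t.smg_genes)):
            assert ids <= universe
        assert t.exclusive_mutation_gene in universe
        assert t.imbalance_driver_gene in universe
        for c, n, _ in t.ncrna_pairs:
            assert c in universe and n in universe

    def test_pair_ncrnas_within_100kb(self, tumor, annotation):
        g = annotation.genes.set_index("gene_id")
        for c, n, _ in tumor.truth.ncrna_pairs:
            assert g.loc[c, "chrom"] == g.loc[n, "chrom"]
            gap = max(g.loc[n, "start"] - g.loc[c, "end"],
                      g.loc[c, "start"] - g.loc[n, "end"], 0)
            assert gap < 100_000


class TestPlantedStatistics:
    def test_activation_fraction_in_binomial_interval(self):
        cfg = _tiny(21, n_genes=60, cohort_size=1000)
        ann, _ = sd.generate_reference(cfg)
        tb = sd.generate_tumor_cohort(cfg, ann)
        lo, hi = binom_interval_99(1000, cfg.ee_frequency)
        for g in tb.truth.activation.index:
            assert lo <= tb.truth.activation.loc[g].sum() <= hi

    def test_full_exclusivity_zero_overlap(self):
        cfg = _tiny(22, exclusivity_strength=1.0)
        ann, _ = sd.generate_reference(cfg)
        tb = sd.generate_tumor_cohort(cfg, ann)
        excl = tb.truth.exclusive_mutation_gene
        mutated = set(tb.mutations.loc[tb.mutations["Hugo_Symbol"] == excl,
                                       "Tumor_Sample_Barcode"])
        act = tb.truth.activation.iloc[0]
        assert mutated
        assert not (mutated & set(act.index[act]))

    def test_no_exclusivity_has_overlap_eventually(self):
        # with strength 0 the mutated set ignores activation; over several
        # seeds an overlap must appear
        overlaps = 0
        for seed in range(5):
            cfg = _tiny(30 + seed, exclusivity_strength=0.0, ee_frequency=0.3,
                        smg_mutation_rate=0.4)
            ann, _ = sd.generate_reference(cfg)
            tb = sd.generate_tumor_cohort(cfg, ann)
            excl = tb.truth.exclusive_mutation_gene
            mutated = set(tb.mutations.loc[tb.mutations["Hugo_Symbol"] == excl,
                                           "Tumor_Sample_Barcode"])
            act = tb.truth.activation.iloc[0]
            overlaps += len(mutated & set(act.index[act]))
        assert overlaps > 0

    def test_methylation_null_gives_uniform_pvalues(self):
        # with zero planted effect the per-gene EE-vs-non-EE beta tests
        # must be calibrated
        from scipy import stats as sps

        from ctcaller import methassoc

        pvals = []
        for seed in range(4):
            cfg = _tiny(50 + seed, methylation_effect=0.0, n_genes=120,
                        n_planted_tsg=20, n_planted_ee_genes=8, n_ct_ncrna_pairs=0,
                        cohort_size=400, genome_length=60_000_000)
            ann, _ = sd.generate_reference(cfg)
            tb = sd.generate_tumor_cohort(cfg, ann)
            out = methassoc.per_gene_methylation_tests(
                tb.methylation, tb.truth.activation,
                list(tb.truth.activation.index),
            )
            pvals.extend(out.loc[out["testable"], "p_value"].tolist())
        assert len(pvals) >= 25
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_element_rates_equal_at_enrichment_one(self):
        cfg = _tiny(60, n_genes=100, n_planted_tsg=10, n_planted_ee_genes=2,
                    n_ct_ncrna_pairs=0, element_enrichment=1.0,
                    element_background_rate=0.3, genome_length=60_000_000)
        ann, el = sd.generate_reference(cfg)
        promoters = el[el["kind"] == "promoter"]
        from ctcaller import enrichment as en

        mapping = en.assign_elements(ann.genes, promoters)
        planted = set(ann.planted("is_planted_tsg"))
        background = set(ann.genes["gene_id"]) - planted
        hit = mapping.genes_with("promoter")
        p1 = len(planted & hit) / len(planted)
        p2 = len(background & hit) / len(background)
        # two-proportion comparison: must not differ beyond binomial noise
        from ctcaller import stats as cstats

        res = cstats.fisher_2x2(
            [[len(planted & hit), len(planted - hit)],
             [len(background & hit), len(background - hit)]]
        )
        assert res.p_value > 0.01
        assert abs(p1 - p2) < 0.35
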