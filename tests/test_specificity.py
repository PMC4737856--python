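"""SPM scoring and gene/protein classification tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcaller import specificity as sp


TISSUES_25 = ["testis"] + [f"t{i}" for i in range(24)]


class TestComputeSpm:
    def test_exclusive_expression_is_one(self):
        x = [10.0] + [0.0] * 24
        assert sp.compute_spm(x, TISSUES_25) == 1.0

    def test_all_zero_is_zero(self):
        assert sp.compute_spm([0.0] * 25, TISSUES_25) == 0.0

    def test_cosine_values(self):
        assert sp.compute_spm([3.0, 4.0], ["testis", "t0"]) == pytest.approx(0.6)
        assert sp.compute_spm([1.0, 1.0, 1.0, 1.0], ["testis", "a", "b", "c"]) == pytest.approx(0.5)

    def test_housekeeping_is_inverse_sqrt_n(self):
        for n in (4, 9, 16, 25):
            tissues = ["testis"] + [f"t{i}" for i in range(n - 1)]
            assert sp.compute_spm([7.0] * n, tissues) == pytest.approx(1 / math.sqrt(n))

    def test_validation(self):
        with pytest.raises(ValueError):
            sp.compute_spm([1.0, -0.5], ["testis", "t0"])
        with pytest.raises(ValueError):
            sp.compute_spm([1.0, 2.0], ["liver", "t0"])

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=30), st.floats(0.001, 1000))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_range_and_scale_invariance(self, values, scale):
        tissues = ["testis"] + [f"t{i}" for i in range(len(values) - 1)]
        s = sp.compute_spm(values, tissues)
        assert 0.0 <= s <= 1.0 + 1e-12
        scaled = [v * scale for v in values]
        assert sp.compute_spm(scaled, tissues) == pytest.approx(s, abs=1e-9)

    def test_one_iff_exclusive(self):
        assert sp.compute_spm([5.0, 0.0, 0.0], ["testis", "a", "b"]) == 1.0
        assert sp.compute_spm([5.0, 1e-3, 0.0], ["testis", "a", "b"]) < 1.0

    def test_matrix_profile_matches_scalar(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(
            rng.uniform(0, 100, (20, 5)),
            index=[f"g{i}" for i in range(20)],
            columns=["testis", "a", "b", "c", "d"],
        )
        prof = sp.spm_profile(mat)
        for g in mat.index:
            assert prof[g] == pytest.approx(
                sp.compute_spm(mat.loc[g].to_numpy(), list(mat.columns))
            )


def _profile(g, h, nj, tmax=None, gid="g"):
    return sp.SpecificityProfile(gid, g, h, nj, tmax)


class TestClassifyGene:
    @pytest.mark.parametrize(
        "spms,biotype,expected",
        [
            ((0.95, 0.95, 0.95), "coding", "C1"),
            ((0.95, 0.95, 0.95), "noncoding", "C2"),
            ((0.95, 0.95, 0.5), "coding", "C3"),
            ((0.95, 0.5, 0.95), "coding", "C3"),
            ((0.95, 0.95, 0.5), "noncoding", "C4"),
            ((0.95, 0.5, 0.5), "coding", "C5"),
            ((0.95, 0.5, 0.5), "noncoding", "C5"),
        ],
    )
    def test_rule_table(self, spms, biotype, expected):
        assert sp.classify_gene(_profile(*spms), biotype).category == expected

    @pytest.mark.parametrize("tmax,expected", [(0.95, "C6a"), (0.5, "C6b")])
    def test_transcript_level_split(self, tmax, expected):
        assert sp.classify_gene(_profile(0.5, 0.95, 0.95, tmax), "coding").category == expected

    def test_threshold_is_strict(self):
        # exactly 0.9 does not pass the > 0.9 rule
        assert sp.classify_gene(_profile(0.9, 0.95, 0.95, 0.5), "coding").category == "C6b"
        assert sp.classify_gene(_profile(0.95, 0.9, 0.9), "coding").category == "C5"

    def test_known_ct_rescue(self):
        got = sp.classify_gene(
            _profile(0.0, 0.95, 0.95), "coding", known_ct=True, has_identical_copies=True
        )
        assert got.category == "C1"
        # without identical copies the rescue does not apply
        got2 = sp.classify_gene(
            _profile(0.0, 0.95, 0.95, 0.5), "coding", known_ct=True, has_identical_copies=False
        )
        assert got2.category == "C6b"

    def test_missing_spm_is_indeterminate(self):
        got = sp.classify_gene(_profile(0.95, None, 0.95), "coding")
        assert got.category == "indeterminate"
        got = sp.classify_gene(_profile(0.5, 0.95, 0.95, None), "coding")
        assert got.category == "indeterminate"

    def test_categories_partition_random_universe(self):
        rng = np.random.default_rng(9)
        counts = {}
        n = 2000
        for i in range(n):
            spms = rng.uniform(0, 1, 4)
            # push some mass near the threshold to hit every branch
            spms = np.where(rng.random(4) < 0.5, spms, 0.85 + 0.15 * spms)
            cat = sp.classify_gene(
                _profile(*spms[:3], spms[3]),
                "coding" if rng.random() < 0.5 else "noncoding",
            ).category
            counts[cat] = counts.get(cat, 0) + 1
        assert sum(counts.values()) == n
        assert set(counts) <= set(sp.CATEGORIES)


class TestClassifyProtein:
    def test_unique_peptides_tsp(self):
        assert sp.classify_protein(0.95, [0.95, 0.8], True) == "TSP"
        assert sp.classify_protein(0.5, [0.95], True) == "non_TSP"

    def test_shared_peptides_only(self):
        assert sp.classify_protein(None, [0.95, 0.92], False) == "testis_specific_peptide"
        assert sp.classify_protein(None, [0.5, 0.4], False) == "non_TSP"

    def test_no_data(self):
        assert sp.classify_protein(None, [], False) == "no_data"

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            sp.classify_protein(None, [0.95], True)
        with pytest.raises(ValueError):
            sp.classify_protein(0.95, [0.95], False)


class TestOnSynthPanels:
    def test_planted_tsgs_recovered(self, annotation, classification):
        planted = set(annotation.planted("is_planted_tsg"))
        called = set(classification.index[classification["category"].isin(["C1", "C2"])])
        assert called == planted  # full recovery, no false positives

    def test_c6a_genes_detected_via_transcripts(self, annotation, classification):
        c6a = annotation.planted("is_planted_c6a")
        assert (classification.loc[c6a, "category"] == "C6a").all()

    def test_category_counts_partition_universe(self, classification):
        counts = classification["category"].value_counts()
        assert counts.sum() == len(classification)
        assert set(counts.index) <= set(sp.CATEGORIES)

    def test_noiseless_spm_exactly_one(self, small_config):
        from ctcaller import synthdata as sd
        from dataclasses import replace

        cfg = replace(small_config, leak_level=0.0, n_genes=80, seed=11)
        ann, _ = sd.generate_reference(cfg)
        panels = sd.generate_normal_panels(cfg, ann)
        planted = ann.planted("is_planted_tsg")
        for key in ("gtex", "hbm", "njmu"):
            prof = sp.spm_profile(panels.panels[key])
            assert (prof.loc[planted] == 1.0).all()

    def test_shared_peptide_only_protein_class(self, small_config, annotation, panels):
        from ctcaller import synthdata as sd

        shared = sd._peptide_shared_only(small_config, annotation)
        prot = sp.classify_proteins(panels.peptides, panels.proteome_tissues)
        assert (prot.loc[shared, "protein_class"] == "testis_specific_peptide").all()
        assert not prot.loc[shared, "has_unique_peptides"].any()
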