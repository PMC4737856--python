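import pandas as pd
import pytest

from ctcaller import synthdata as sd
from ctcaller import specificity as sp


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured simulation used by several suites."""
    return sd.SimulationConfig(seed=7, n_genes=300, cohort_size=120)


@pytest.fixture(scope="session")
def reference(small_config):
    return sd.generate_reference(small_config)


@pytest.fixture(scope="session")
def annotation(reference):
    return reference[0]


@pytest.fixture(scope="session")
def elements(reference):
    return reference[1]


@pytest.fixture(scope="session")
def panels(small_config, annotation):
    return sd.generate_normal_panels(small_config, annotation)


@pytest.fixture(scope="session")
def tumor(small_config, annotation):
    return sd.generate_tumor_cohort(small_config, annotation)


@pytest.fixture(scope="session")
def classification(annotation, panels):
    biotypes = pd.Series(
        annotation.genes["biotype"].to_numpy(),
        index=annotation.genes["gene_id"].to_numpy(),
    )
    tx_map = pd.Series(
        annotation.transcripts["gene_id"].to_numpy(),
        index=annotation.transcripts["transcript_id"].to_numpy(),
    )
    cls = sp.classify_genes(
        panels.panels, panels.transcript_panel, tx_map, biotypes=biotypes
    )
    prot = sp.classify_proteins(panels.peptides, panels.proteome_tissues)
    cls["protein_class"] = prot["protein_class"].reindex(cls.index).fillna("no_data")
    return cls
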