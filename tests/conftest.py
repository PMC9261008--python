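import warnings

import numpy as np
import pandas as pd
import pytest

import ftdprot as fp

warnings.filterwarnings("ignore", message=".*all-missing rows.*")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group cohort with planted effects and full missingness model."""
    cfg = fp.SimConfig(
        n_samples_per_group=5, n_proteins=60, de_fraction=0.2, de_log2fc=2.0,
        n_tech_replicates=2, seed=11,
    )
    table, metadata, pep2prot, truth = fp.generate_dia_cohort(cfg)
    return cfg, table, metadata, pep2prot, truth


@pytest.fixture(scope="session")
def clean_protein_matrix():
    """Protein-level matrix (1 peptide, 1 fraction, no missingness)."""
    cfg = fp.SimConfig(
        n_samples_per_group=6, n_proteins=80, peptides_per_protein_range=(1, 1),
        n_fractions=1, de_fraction=0.25, de_log2fc=2.0, sample_scale_sd=0.0,
        noise_sd=0.3, missingness_midpoint=-1e9, seed=7,
    )
    table, metadata, pep2prot, truth = fp.generate_dia_cohort(cfg)
    prot = fp.rollup_proteins(
        fp.rollup_fractions(fp.peptide_fraction_matrix(table)), pep2prot
    )
    design = fp.GroupDesign(metadata["group"], "NDC", "FTD")
    return prot, design, truth


@pytest.fixture(scope="session")
def sc_reference():
    matrix, labels, truth = fp.generate_sc_reference(
        n_cells_per_type=40, n_genes=240, n_marker_per_type=12,
        marker_enrichment=50.0, n_types=3, seed=5,
    )
    return matrix, labels, truth


@pytest.fixture(scope="session")
def spec_matrix(sc_reference):
    matrix, labels, _ = sc_reference
    return fp.compute_specificity(matrix, labels)


@pytest.fixture(scope="session")
def ontology_fixture():
    dag, sets = fp.generate_ontology_fixture(n_terms=30, max_depth=3, n_genes=120, seed=3)
    return dag, sets
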