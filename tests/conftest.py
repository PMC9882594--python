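import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from xenocensus import GeneratorConfig, TaggedCountMatrix, generate_barnyard
from xenocensus.reference import GeneRecord, panel_to_var


def make_matrix(counts, species_tags, mito=None, barcodes=None) -> TaggedCountMatrix:
    """Build a TaggedCountMatrix from a dense array and per-gene tags."""
    counts = np.asarray(counts, dtype=np.int64)
    n_cells, n_genes = counts.shape
    mito = [False] * n_genes if mito is None else mito
    panel = [
        GeneRecord(f"g{i:04d}", f"{'MT-' if mito[i] else ''}G{i:04d}", tag, mito[i])
        for i, tag in enumerate(species_tags)
    ]
    var = panel_to_var(panel)
    if barcodes is None:
        barcodes = [f"cell{i:04d}" for i in range(n_cells)]
    return TaggedCountMatrix(sp.csr_matrix(counts), pd.Index(barcodes), var)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Fast but fully featured generator config (homologs, soup, doublets)."""
    return GeneratorConfig(
        n_cells=300,
        n_genes_per_species=300,
        n_homolog_pairs=10,
        cross_map_prob=0.02,
        soup_fraction=0.02,
        doublet_rate=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_barnyard(small_config):
    matrix, truth = generate_barnyard(small_config)
    return matrix, truth.set_index("barcode")


@pytest.fixture(scope="session")
def clean_config() -> GeneratorConfig:
    """No leakage channels: cross-mapping, soup and doublets all off."""
    return GeneratorConfig(
        n_cells=200,
        n_genes_per_species=300,
        n_homolog_pairs=10,
        cross_map_prob=0.0,
        soup_fraction=0.0,
        doublet_rate=0.0,
        dying_cell_fraction=0.0,
        seed=21,
    )


@pytest.fixture(scope="session")
def clean_barnyard(clean_config):
    matrix, truth = generate_barnyard(clean_config)
    return matrix, truth.set_index("barcode")
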