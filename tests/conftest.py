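import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from senindex import CountMatrix, NormalizedMatrix, fixture_small, normalize


def make_counts(counts, gene_names=None, cell_names=None, biotype="protein_coding",
                is_mito=None):
    """Build a CountMatrix from a dense cells x genes array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_names = gene_names or [f"g{j + 1}" for j in range(n_genes)]
    cell_names = cell_names or [f"c{i + 1}" for i in range(n_cells)]
    genes = pd.DataFrame(index=pd.Index(gene_names, name="symbol"))
    genes["biotype"] = biotype if isinstance(biotype, str) else list(biotype)
    if is_mito is not None:
        genes["is_mito"] = is_mito
    cells = pd.DataFrame(index=pd.Index(cell_names, name="barcode"))
    return CountMatrix(sp.csr_matrix(counts), genes, cells)


def make_norm(values, gene_names=None, cell_names=None):
    """Build a NormalizedMatrix directly from a dense cells x genes array."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    gene_names = gene_names or [f"g{j + 1}" for j in range(n_genes)]
    cell_names = cell_names or [f"c{i + 1}" for i in range(n_cells)]
    genes = pd.DataFrame(index=pd.Index(gene_names, name="symbol"))
    cells = pd.DataFrame(index=pd.Index(cell_names, name="barcode"))
    return NormalizedMatrix(sp.csr_matrix(values), genes, cells)


@pytest.fixture(scope="session")
def fixture_data():
    return fixture_small()


@pytest.fixture(scope="session")
def fixture_norm(fixture_data):
    cm, _ = fixture_data
    return normalize(cm)
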