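import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from inktmap.io_formats import CountMatrix, NormalizedMatrix, PipelineConfig
from inktmap.preprocess import HVGTable


@pytest.fixture
def config():
    return PipelineConfig()


def make_counts(dense, gene_names=None, barcodes=None, mito_prefix="mt-",
                cell_meta=None):
    """Build a CountMatrix from a dense cells-x-genes integer array."""
    dense = np.asarray(dense, dtype=np.int64)
    n_cells, n_genes = dense.shape
    if gene_names is None:
        gene_names = [f"G{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"C{i}" for i in range(n_cells)]
    is_mito = np.array([g.lower().startswith(mito_prefix) for g in gene_names])
    return CountMatrix(
        counts=sp.csr_matrix(dense),
        gene_names=list(gene_names),
        barcodes=list(barcodes),
        is_mito=is_mito,
        cell_meta=cell_meta,
    )


def make_norm(values, gene_names=None, barcodes=None, pseudocount=1.0):
    """Build a NormalizedMatrix directly from dense log-expression values."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    if gene_names is None:
        gene_names = [f"G{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"C{i}" for i in range(n_cells)]
    return NormalizedMatrix(
        values=values,
        gene_names=list(gene_names),
        barcodes=list(barcodes),
        size_factors=np.ones(n_cells),
        pseudocount=pseudocount,
    )


def hvg_all(gene_names):
    """An HVGTable selecting every listed gene."""
    n = len(gene_names)
    return HVGTable(
        pd.DataFrame(
            {
                "mean": np.zeros(n),
                "total_var": np.ones(n),
                "trend_var": np.zeros(n),
                "bio_var": np.ones(n),
                "pvalue": np.zeros(n),
                "fdr": np.zeros(n),
                "selected": np.ones(n, dtype=bool),
            },
            index=pd.Index(gene_names, name="gene"),
        )
    )
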