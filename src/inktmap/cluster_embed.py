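"""PCA, shared-nearest-neighbor Leiden clustering, and UMAP embedding.

The reference dataset is reduced to its first ``n_pcs`` principal components
over selected HVGs, clustered by modularity community detection on an SNN
graph (Jaccard weights over k = 20 nearest neighbors), and embedded in 2-D
with UMAP. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_formats import NormalizedMatrix, PipelineConfig
from .preprocess import HVGTable

SNN_K = 20  # neighbors for the SNN graph (common default)


@dataclass
class Embedding:
    """Per-cell PC coordinates, 2-D embedding, and cluster labels."""

    barcodes: list[str]
    pcs: np.ndarray  # cells x n_pcs
    umap: np.ndarray | None = None  # cells x 2
    labels: np.ndarray | None = None  # int, contiguous from 0
    loadings: np.ndarray | None = None  # genes x n_pcs
    explained_variance: np.ndarray | None = None
    hvg_genes: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return 0 if self.labels is None else int(self.labels.max()) + 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.pcs,
            index=pd.Index(self.barcodes, name="barcode"),
            columns=[f"PC{i + 1}" for i in range(self.pcs.shape[1])],
        )
        if self.umap is not None:
            df["UMAP1"], df["UMAP2"] = self.umap[:, 0], self.umap[:, 1]
        if self.labels is not None:
            df["cluster"] = self.labels
        return df


def reduce_pca(
    norm: NormalizedMatrix,
    hvg_table: HVGTable,
    config: PipelineConfig,
    scale: bool = True,
) -> Embedding:
    """Project the (centered, unit-scaled) HVG submatrix onto top PCs.

    The sign of each component is fixed by making its largest-magnitude
    loading positive, so results are reproducible across runs and SVD
    backends.
    """
    genes = hvg_table.selected_genes
    if len(genes) < config.n_pcs:
        raise ValueError(
            f"need >= n_pcs={config.n_pcs} selected HVGs, got {len(genes)}"
        )
    idx = [norm.gene_names.index(g) for g in genes]
    x = norm.values[:, idx].astype(float)
    if config.n_pcs > min(x.shape):
        raise ValueError(f"n_pcs={config.n_pcs} exceeds data rank bound {min(x.shape)}")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    pca = PCA(n_components=config.n_pcs, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()  # genes x n_pcs
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return Embedding(
        barcodes=list(norm.barcodes),
        pcs=scores,
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        hvg_genes=list(genes),
    )


def _snn_graph(pcs: np.ndarray, k: int) -> igraph.Graph:
    n = pcs.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)  # includes self at distance 0
    rows = np.repeat(np.arange(n), k + 1)
    adj = sp.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n), dtype=np.float64
    )
    inter = adj @ adj.T  # shared-neighbor counts (sets include self)
    inter = sp.triu(inter, k=1).tocoo()
    union = 2 * (k + 1) - inter.data
    jaccard = inter.data / union
    keep = jaccard > 0
    edges = list(zip(inter.row[keep].tolist(), inter.col[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def cluster_snn(pcs: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Leiden modularity clustering of the SNN graph at ``cluster_resolution``.

    Labels are relabeled contiguously from 0 in decreasing cluster size
    (ties broken by smallest member index), deterministic given the seed.
    """
    n = pcs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    g = _snn_graph(pcs, SNN_K)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=config.cluster_resolution,
        seed=config.seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {c: i for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw], dtype=int)


def embed_2d(pcs: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """UMAP to 2-D, deterministic given the seed."""
    import umap  # deferred: numba compilation is slow at import

    n = pcs.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to embed")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        warnings.filterwarnings("ignore", message=".*random_state.*")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(15, n - 1),
            random_state=config.seed,
        )
        coords = reducer.fit_transform(pcs)
    return np.asarray(coords, dtype=float)


def cluster_and_embed(
    norm: NormalizedMatrix,
    hvg_table: HVGTable,
    config: PipelineConfig,
    with_umap: bool = True,
) -> Embedding:
    """Convenience wrapper: PCA -> Leiden labels -> (optional) UMAP."""
    emb = reduce_pca(norm, hvg_table, config)
    emb.labels = cluster_snn(emb.pcs, config)
    if with_umap:
        emb.umap = embed_2d(emb.pcs, config)
    return emb
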