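"""Correlation-kNN reference mapping and per-group mapping ratios.

Each query cell is compared with every reference cell by Pearson correlation
over the reference HVG set (log-normalized values); its ``k_project``
highest-correlation reference cells define its projected 2-D coordinate (the
unweighted mean of their embedding coordinates) and its assigned reference
subpopulation (majority vote among their cluster labels; ties go to the tied
label with the highest mean correlation, then the lowest label index).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_embed import Embedding
from .io_formats import NormalizedMatrix, PipelineConfig
from .preprocess import HVGTable

logger = logging.getLogger(__name__)


@dataclass
class ProjectionResult:
    barcodes: list[str]
    neighbor_indices: np.ndarray  # queries x k (reference row indices)
    neighbor_correlations: np.ndarray  # queries x k
    coordinates: np.ndarray  # queries x 2
    assigned_label: np.ndarray  # int, -1 for unmappable
    mappable: np.ndarray  # bool per query
    reference_labels: np.ndarray  # cluster labels of the reference
    shared_genes: list[str]
    coverage: float  # fraction of reference HVGs found in the query

    def to_frame(self) -> pd.DataFrame:
        k = self.neighbor_indices.shape[1]
        df = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        for j in range(k):
            df[f"nn{j + 1}"] = self.neighbor_indices[:, j]
            df[f"corr{j + 1}"] = self.neighbor_correlations[:, j]
        df["x"], df["y"] = self.coordinates[:, 0], self.coordinates[:, 1]
        df["assigned_label"] = self.assigned_label
        df["mappable"] = self.mappable
        return df


def _row_standardize(x: np.ndarray):
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    return centered / safe[:, None], ok


def _majority_label(labels: np.ndarray, corrs: np.ndarray) -> int:
    uniq, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    tied = uniq[counts == top]
    if len(tied) == 1:
        return int(tied[0])
    mean_corr = np.array([corrs[labels == lab].mean() for lab in tied])
    best = mean_corr.max()
    # Residual tie: lowest label index (uniq is sorted).
    return int(tied[np.flatnonzero(mean_corr >= best - 1e-12)[0]])


def project_cells(
    ref_norm: NormalizedMatrix,
    ref_embedding: Embedding,
    ref_hvgs: HVGTable,
    query_norm: NormalizedMatrix,
    config: PipelineConfig,
) -> ProjectionResult:
    """Map query cells onto the reference embedding via Pearson-correlation kNN.

    Reference HVGs absent from the query are dropped (coverage is logged and
    must stay >= 50%). Query cells with zero variance over the shared genes
    are flagged unmappable and excluded from downstream ratios.
    """
    if ref_embedding.labels is None or ref_embedding.umap is None:
        raise ValueError("reference embedding must carry cluster labels and UMAP")
    n_ref = len(ref_norm.barcodes)
    k = config.k_project
    if n_ref < k:
        raise ValueError(f"need >= k_project={k} reference cells, got {n_ref}")

    hvg_genes = ref_hvgs.selected_genes
    query_set = set(query_norm.gene_names)
    shared = [g for g in hvg_genes if g in query_set]
    coverage = len(shared) / len(hvg_genes) if hvg_genes else 0.0
    logger.info("projection gene coverage: %.3f (%d/%d)", coverage, len(shared), len(hvg_genes))
    if coverage < 0.5:
        raise ValueError(
            f"query covers only {coverage:.0%} of reference HVGs (need >= 50%)"
        )

    ref_idx = [ref_norm.gene_names.index(g) for g in shared]
    q_name_to_idx = {g: i for i, g in enumerate(query_norm.gene_names)}
    query_idx = [q_name_to_idx[g] for g in shared]
    r = ref_norm.values[:, ref_idx].astype(np.float64)
    q = query_norm.values[:, query_idx].astype(np.float64)

    rz, r_ok = _row_standardize(r)
    qz, q_ok = _row_standardize(q)
    if not q_ok.all():
        warnings.warn(
            f"{int((~q_ok).sum())} query cell(s) with zero variance flagged unmappable",
            UserWarning,
        )
    corr = qz @ rz.T
    corr[:, ~r_ok] = 0.0  # degenerate reference cells never win

    # Highest correlations first; stable sort breaks ties by reference index.
    order = np.argsort(-corr, axis=1, kind="stable")[:, :k]
    nn_corr = np.take_along_axis(corr, order, axis=1)
    coords = ref_embedding.umap[order].mean(axis=1)
    ref_labels = np.asarray(ref_embedding.labels)

    n_q = q.shape[0]
    assigned = np.full(n_q, -1, dtype=int)
    for i in range(n_q):
        if q_ok[i]:
            assigned[i] = _majority_label(ref_labels[order[i]], nn_corr[i])
    coords[~q_ok] = np.nan

    return ProjectionResult(
        barcodes=list(query_norm.barcodes),
        neighbor_indices=order,
        neighbor_correlations=nn_corr,
        coordinates=coords,
        assigned_label=assigned,
        mappable=q_ok,
        reference_labels=ref_labels,
        shared_genes=shared,
        coverage=coverage,
    )


def mapping_ratio(result: ProjectionResult, group_by) -> pd.DataFrame:
    """Per query group, the fraction of mapped cells assigned to each
    reference subpopulation (rows sum to 1).

    Groups whose cells are all unmappable are omitted with a warning.
    """
    groups = np.asarray(group_by)
    if groups.shape[0] != len(result.barcodes):
        raise ValueError("group_by length must match the number of query cells")
    n_labels = int(result.reference_labels.max()) + 1
    rows = {}
    for g in pd.unique(groups):
        mask = (groups == g) & result.mappable
        if not mask.any():
            warnings.warn(f"group {g!r}: all cells unmappable; omitted", UserWarning)
            continue
        counts = np.bincount(result.assigned_label[mask], minlength=n_labels)
        rows[g] = counts / counts.sum()
    if not rows:
        raise ValueError("no group had any mappable cell")
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = [f"cluster{c}" for c in range(n_labels)]
    df.index.name = "group"
    return df
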