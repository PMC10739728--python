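"""Reference experiments on synthetic data with known ground truth.

These functions define the study conditions under which the pipeline's
claims are checked: recovery of simulated subpopulations by clustering,
qualitative reproduction of the cross-tissue mapping-ratio pattern (cells
from a tissue lacking a reference-specific subpopulation should barely map
to it), type-I calibration of HVG selection under an all-null simulation,
recovery of engineered clonotype sharing, and recovery of an ordered lineage.
They are used by the test suite, the acceptance script, and the analysis
drivers alike.
"""

from __future__ import annotations

import numpy as np
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from . import preprocess
from .cluster_embed import Embedding, cluster_snn, embed_2d, reduce_pca
from .io_formats import CountMatrix, PipelineConfig
from .projection import mapping_ratio, project_cells
from .synthdata import SimParams, simulate_counts


def _qc_norm_hvg(matrix, truth, config):
    filtered, _ = preprocess.filter_cells(matrix, config)
    sf = preprocess.compute_size_factors(filtered)
    norm = preprocess.lognormalize(filtered, sf, config)
    hvgs = preprocess.select_hvgs(norm, config)
    truth_sub = truth.cells.loc[filtered.barcodes]
    return filtered, norm, hvgs, truth_sub


def clustering_recovery(seed: int, n_subpops: int = 4, cells_per_subpop: int = 200,
                        n_genes: int = 1000, marker_log2fc: float = 4.0) -> float:
    """ARI between Leiden clusters and true subpopulations.

    One tissue, equal subpopulation proportions, 50 markers per
    subpopulation at the given log2 fold change.
    """
    names = [f"S{i}" for i in range(n_subpops)]
    params = SimParams(
        n_tissues=1,
        subpop_spec=[(n, (1.0 / n_subpops,)) for n in names],
        n_cells_per_tissue=n_subpops * cells_per_subpop,
        n_genes=n_genes,
        marker_log2fc=marker_log2fc,
        seed=seed,
    )
    config = PipelineConfig(seed=seed)
    matrix, truth = simulate_counts(params)
    _, norm, hvgs, truth_sub = _qc_norm_hvg(matrix, truth, config)
    emb = reduce_pca(norm, hvgs, config)
    labels = cluster_snn(emb.pcs, config)
    return float(adjusted_rand_score(truth_sub["subpop"].to_numpy(), labels))


def projection_mapping_experiment(seed: int, n_cells_per_tissue: int = 400,
                                  n_genes: int = 1000) -> dict:
    """Cross-tissue reference mapping under an engineered design.

    The reference tissue T0 carries a tissue-specific subpopulation S
    (marker log2FC = 4) plus shared subpopulations U and P17; the query
    tissue T1 lacks S. Returns the fraction of query cells mapped to the
    S-like reference cluster(s) and to the shared-U cluster(s).
    """
    params = SimParams(
        n_tissues=2,
        subpop_spec=[
            ("U", (0.50, 0.90)),
            ("S", (0.30, 0.00)),
            ("P17", (0.20, 0.10)),
        ],
        n_cells_per_tissue=n_cells_per_tissue,
        n_genes=n_genes,
        marker_log2fc=4.0,
        seed=seed,
    )
    config = PipelineConfig(seed=seed)
    matrix, truth = simulate_counts(params)
    filtered, norm, _, truth_sub = _qc_norm_hvg(matrix, truth, config)

    ref_mask = (truth_sub["tissue"] == "T0").to_numpy()
    from .cli import _subset_norm  # shared helper

    ref_norm = _subset_norm(norm, ref_mask)
    query_norm = _subset_norm(norm, ~ref_mask)
    ref_hvgs = preprocess.select_hvgs(ref_norm, config)
    emb = reduce_pca(ref_norm, ref_hvgs, config)
    emb.labels = cluster_snn(emb.pcs, config)
    emb.umap = embed_2d(emb.pcs, config)

    result = project_cells(ref_norm, emb, ref_hvgs, query_norm, config)
    ratios = mapping_ratio(
        result, truth_sub.loc[~ref_mask, "tissue"].to_numpy()
    ).loc["T1"]

    # Annotate reference clusters by their majority true subpopulation.
    ref_truth = truth_sub.loc[ref_mask, "subpop"].to_numpy()
    cluster_subpop = {}
    for c in range(emb.n_clusters):
        vals, counts = np.unique(ref_truth[emb.labels == c], return_counts=True)
        cluster_subpop[c] = vals[np.argmax(counts)]
    ratio_to = {"U": 0.0, "S": 0.0, "P17": 0.0}
    for c, sub in cluster_subpop.items():
        ratio_to[sub] += float(ratios[f"cluster{c}"])
    return {
        "ratio_to_specific": ratio_to["S"],
        "ratio_to_shared": ratio_to["U"],
        "cluster_subpop": cluster_subpop,
        "n_query": int((~ref_mask).sum()),
    }


def hvg_null_fp_rate(seed: int, n_genes: int = 2000, n_cells: int = 500) -> float:
    """Raw p < 0.05 rate of HVG selection when every gene is iid Poisson."""
    import scipy.sparse as sp

    rng = np.random.default_rng(seed)
    counts = rng.poisson(1.0, size=(n_cells, n_genes))
    matrix = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_names=[f"G{i}" for i in range(n_genes)],
        barcodes=[f"C{i}" for i in range(n_cells)],
        is_mito=np.zeros(n_genes, dtype=bool),
    )
    config = PipelineConfig(min_umi=0)
    sf = preprocess.compute_size_factors(matrix)
    norm = preprocess.lognormalize(matrix, sf, config)
    hvgs = preprocess.select_hvgs(norm, config)
    return float((hvgs.table["pvalue"] < 0.05).mean())


def projection_bruteforce_oracle(ref_values: np.ndarray, ref_umap: np.ndarray,
                                 query_values: np.ndarray, k: int):
    """Double-loop Pearson reference mapping (independent oracle).

    Correlates every query against every reference cell with
    ``scipy.stats.pearsonr``, takes the k highest (ties by reference index),
    and averages their 2-D coordinates.
    """
    n_q, n_r = query_values.shape[0], ref_values.shape[0]
    corr = np.empty((n_q, n_r))
    for i in range(n_q):
        for j in range(n_r):
            corr[i, j] = scipy.stats.pearsonr(query_values[i], ref_values[j])[0]
    neighbors = np.empty((n_q, k), dtype=int)
    ncorr = np.empty((n_q, k))
    coords = np.empty((n_q, 2))
    for i in range(n_q):
        order = sorted(range(n_r), key=lambda j: (-corr[i, j], j))[:k]
        neighbors[i] = order
        ncorr[i] = corr[i, order]
        coords[i] = ref_umap[order].mean(axis=0)
    return neighbors, ncorr, coords


def gradient_lineage_embedding(seed: int, cells_per_cluster: int = 60,
                               spacing: float = 3.0, noise: float = 0.5) -> Embedding:
    """Three ordered clusters along a 1-D latent gradient in 2-D."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [spacing, 0.3], [2 * spacing, 0.0]])
    coords, labels = [], []
    for c, center in enumerate(centers):
        coords.append(center + rng.normal(0, noise, size=(cells_per_cluster, 2)))
        labels.extend([c] * cells_per_cluster)
    coords = np.vstack(coords)
    return Embedding(
        barcodes=[f"C{i}" for i in range(len(labels))],
        pcs=coords.copy(),
        umap=coords,
        labels=np.asarray(labels),
    )


def shared_clone_experiment(seed: int, n_shared: int = 3):
    """Simulate engineered clonotype sharing and recover it end to end.

    Returns the pairwise shared-count matrix, Jaccard matrix, and the
    expected Jaccard computed by set arithmetic on the generator's truth.
    """
    from .repertoire import call_clonotypes, clonotype_overlap, filter_contigs

    params = SimParams(
        n_tissues=1,
        subpop_spec=[("A", (0.5,)), ("B", (0.5,))],
        n_cells_per_tissue=300,
        n_genes=200,
        shared_clone_spec=[("A", "B", n_shared)],
        fraction_nonproductive=0.05,
        fraction_low_confidence=0.05,
        seed=seed,
    )
    matrix, truth = simulate_counts(params)
    from .synthdata import simulate_tcr

    contigs = simulate_tcr(truth, params)
    table = call_clonotypes(filter_contigs(contigs), matrix.barcodes)
    shared, jaccard, _ = clonotype_overlap(table, truth.cells["subpop"].to_numpy())

    # Independent expectation from the called clonotype sets themselves.
    assigned = table.assigned()
    groups = truth.cells.loc[assigned.index, "subpop"]
    set_a = set(assigned.loc[groups == "A", "clonotype_id"])
    set_b = set(assigned.loc[groups == "B", "clonotype_id"])
    expected_jaccard = len(set_a & set_b) / len(set_a | set_b)
    return shared, jaccard, expected_jaccard


def spanning_tree_bruteforce(coords: np.ndarray) -> float:
    """Exhaustive minimum spanning-tree weight over K <= 8 nodes."""
    from itertools import combinations

    k = coords.shape[0]
    all_edges = [
        (i, j, float(np.linalg.norm(coords[i] - coords[j])))
        for i, j in combinations(range(k), 2)
    ]
    best = np.inf
    for subset in combinations(all_edges, k - 1):
        parent = list(range(k))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b, _ in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            best = min(best, sum(d for _, _, d in subset))
    return best
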