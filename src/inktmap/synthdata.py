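"""Synthetic multi-tissue iNKT scRNA-seq + paired-TCR data with known ground truth.

The generator emulates the structure of a sorted-iNKT single-cell experiment:
several tissues share some subpopulations and possess tissue-specific ones;
UMI counts are negative-binomial with subpopulation marker programs layered on
per-gene baseline means; library sizes vary log-normally; a designated cell
fraction carries inflated mitochondrial expression (QC fodder); every cell has
an invariant TCRα chain and a variable β chain drawn from per-subpopulation
clone pools with Dirichlet-multinomial frequencies (clonal expansion), with
engineered clonotype sharing between designated subpopulations.

Ground truth (tissue, subpopulation, clonotype per cell; marker/mito role per
gene; realized clone tables) is returned alongside, so every downstream stage
of the pipeline is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

# Canonical mouse iNKT invariant alpha chain (Valpha14-Jalpha18).
INVARIANT_ALPHA = ("TRAV11", "TRAJ18", "CVVGDRGSALGRLHF")

_AA = "ACDEFGHIKLMNPQRSTVWY"
_V_BETA = ("TRBV13-1", "TRBV13-2", "TRBV29", "TRBV1")
_J_BETA = ("TRBJ2-1", "TRBJ2-7", "TRBJ1-1")


class ParameterError(ValueError):
    """Raised when simulation parameters violate their invariants."""


def default_subpop_spec() -> list[tuple[str, tuple[float, ...]]]:
    """Two tissues, four subpopulations.

    U is universal (present in both tissues), S is specific to tissue T0
    (the 'adipose-specific' analogue), P17 is shared at lower abundance, and
    X is specific to tissue T1. Proportions loosely follow the observed
    dominance of the universal iNKT1 pool in every organ.
    """
    return [
        ("U", (0.45, 0.70)),
        ("S", (0.30, 0.00)),
        ("P17", (0.25, 0.10)),
        ("X", (0.00, 0.20)),
    ]


@dataclass
class SimParams:
    """Parameters of the synthetic experiment (defaults = study conditions)."""

    n_tissues: int = 2
    subpop_spec: list[tuple[str, tuple[float, ...]]] = field(
        default_factory=default_subpop_spec
    )
    n_cells_per_tissue: int = 600
    n_genes: int = 2000
    n_markers_per_subpop: int = 50
    marker_log2fc: float = 2.0
    baseline_mean_shape: float = 0.5
    baseline_mean_scale: float = 2.0
    nb_dispersion: float = 0.1
    libsize_lognormal_sigma: float = 0.3
    mito_gene_fraction: float = 0.02
    mito_mean_inflation: float = 8.0
    high_mito_cell_fraction: float = 0.05
    clone_dirichlet_alpha: float = 0.5
    n_clones_per_subpop: int = 30
    shared_clone_spec: list[tuple[str, str, int]] = field(default_factory=list)
    fraction_nonproductive: float = 0.05
    fraction_low_confidence: float = 0.05
    conditions: Sequence[str] = ("NCD", "HFD")
    seed: int = 0

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_tissues < 1:
            raise ParameterError("n_tissues must be positive")
        if self.n_cells_per_tissue < 1 or self.n_genes < 1:
            raise ParameterError("cell and gene counts must be positive")
        if self.n_markers_per_subpop < 0:
            raise ParameterError("n_markers_per_subpop must be >= 0")
        if self.marker_log2fc < 0:
            raise ParameterError("marker_log2fc must be >= 0")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        if self.libsize_lognormal_sigma < 0:
            raise ParameterError("libsize_lognormal_sigma must be >= 0")
        if not 0.0 <= self.mito_gene_fraction <= 1.0:
            raise ParameterError("mito_gene_fraction must lie in [0, 1]")
        if self.mito_mean_inflation < 1.0:
            raise ParameterError("mito_mean_inflation must be >= 1")
        if not 0.0 <= self.high_mito_cell_fraction <= 1.0:
            raise ParameterError("high_mito_cell_fraction must lie in [0, 1]")
        if self.clone_dirichlet_alpha <= 0:
            raise ParameterError("clone_dirichlet_alpha must be > 0")
        if self.n_clones_per_subpop < 1:
            raise ParameterError("n_clones_per_subpop must be positive")
        for frac in (self.fraction_nonproductive, self.fraction_low_confidence):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError("contig noise fractions must lie in [0, 1]")
        if not self.subpop_spec:
            raise ParameterError("subpop_spec must not be empty")
        names = [name for name, _ in self.subpop_spec]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate subpopulation ids")
        for name, props in self.subpop_spec:
            if len(props) != self.n_tissues:
                raise ParameterError(
                    f"subpopulation {name!r}: expected {self.n_tissues} "
                    f"per-tissue proportions, got {len(props)}"
                )
            if any(p < 0 for p in props):
                raise ParameterError(f"subpopulation {name!r}: negative proportion")
        mat = np.array([props for _, props in self.subpop_spec], dtype=float)
        sums = mat.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ParameterError(
                f"per-tissue subpopulation proportions must sum to 1, got {sums}"
            )
        subpops = set(names)
        for a, b, n in self.shared_clone_spec:
            if a not in subpops or b not in subpops or a == b:
                raise ParameterError(f"invalid shared_clone_spec entry ({a}, {b}, {n})")
            if n < 0:
                raise ParameterError("shared clone count must be >= 0")

    @property
    def subpop_names(self) -> list[str]:
        return [name for name, _ in self.subpop_spec]

    def streams(self) -> dict[str, np.random.Generator]:
        """One independent RNG stream per logical component.

        Derived from the master seed so that, e.g., adding cells does not
        perturb TCR draws.
        """
        names = ["genes", "cells", "counts", "libsize", "tcr", "noise"]
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SyntheticTruth:
    """Per-cell / per-gene ground truth of one simulated experiment."""

    cells: pd.DataFrame  # index barcode; columns tissue, subpop, condition,
    #                      high_mito, clonotype_id (filled by simulate_tcr)
    genes: pd.DataFrame  # index gene; columns marker_of, is_mito
    clone_tables: pd.DataFrame | None = None  # subpop, clonotype_id, n_cells
    clonotype_keys: pd.DataFrame | None = None  # clonotype_id -> chain fields


def _barcodes(params: SimParams) -> tuple[list[str], np.ndarray]:
    barcodes, tissue_idx = [], []
    for t in range(params.n_tissues):
        for i in range(params.n_cells_per_tissue):
            barcodes.append(f"CELL-T{t}-{i:04d}")
            tissue_idx.append(t)
    return barcodes, np.asarray(tissue_idx)


def simulate_counts(params: SimParams):
    """Draw a gene-by-cell UMI count matrix plus ground truth.

    Counts are NB(mean, dispersion) with
    ``mean = baseline * 2**(marker_log2fc * is_marker) * mito_inflation * libsize``
    and ``variance = mean + mean**2 * dispersion``. Deterministic given
    ``params.seed``.

    Returns ``(CountMatrix, SyntheticTruth)``.
    """
    from .io_formats import CountMatrix  # local import to avoid cycle at import time

    params.validate()
    rng = params.streams()

    n_mito = int(round(params.mito_gene_fraction * params.n_genes))
    gene_names = [f"mt-Mito{i}" for i in range(n_mito)] + [
        f"Gene{i:04d}" for i in range(params.n_genes - n_mito)
    ]
    is_mito = np.zeros(params.n_genes, dtype=bool)
    is_mito[:n_mito] = True

    baseline = rng["genes"].gamma(
        params.baseline_mean_shape, params.baseline_mean_scale, size=params.n_genes
    )
    baseline = np.maximum(baseline, 1e-6)

    # Disjoint marker blocks among non-mito genes.
    marker_of = np.array([""] * params.n_genes, dtype=object)
    names = params.subpop_names
    needed = n_mito + len(names) * params.n_markers_per_subpop
    if needed > params.n_genes:
        raise ParameterError(
            f"n_genes={params.n_genes} too small for {len(names)} subpopulations "
            f"x {params.n_markers_per_subpop} markers + {n_mito} mito genes"
        )
    marker_idx: dict[str, np.ndarray] = {}
    pos = n_mito
    for name in names:
        idx = np.arange(pos, pos + params.n_markers_per_subpop)
        marker_idx[name] = idx
        marker_of[idx] = name
        pos += params.n_markers_per_subpop

    barcodes, tissue_idx = _barcodes(params)
    n_cells = len(barcodes)

    # Subpopulation assignment per tissue.
    prop = np.array([props for _, props in params.subpop_spec], dtype=float)
    subpop = np.empty(n_cells, dtype=object)
    for t in range(params.n_tissues):
        mask = tissue_idx == t
        subpop[mask] = rng["cells"].choice(names, size=mask.sum(), p=prop[:, t])

    condition = rng["cells"].choice(
        list(params.conditions), size=n_cells
    )
    high_mito = rng["cells"].random(n_cells) < params.high_mito_cell_fraction
    lib = np.exp(rng["libsize"].normal(0.0, params.libsize_lognormal_sigma, n_cells))

    # Per-cell mean vectors.
    mean = np.tile(baseline, (n_cells, 1))
    fold = 2.0**params.marker_log2fc
    for name in names:
        rows = np.flatnonzero(subpop == name)
        if rows.size and marker_idx[name].size:
            mean[np.ix_(rows, marker_idx[name])] *= fold
    if n_mito and high_mito.any():
        mean[np.ix_(np.flatnonzero(high_mito), np.flatnonzero(is_mito))] *= (
            params.mito_mean_inflation
        )
    mean *= lib[:, None]

    r = 1.0 / params.nb_dispersion
    p = r / (r + mean)
    counts = rng["counts"].negative_binomial(r, p).astype(np.int64)

    cell_meta = pd.DataFrame(
        {
            "tissue": [f"T{t}" for t in tissue_idx],
            "subpop": subpop,
            "condition": condition,
            "high_mito": high_mito,
            "clonotype_id": [""] * n_cells,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    gene_meta = pd.DataFrame(
        {"marker_of": marker_of, "is_mito": is_mito},
        index=pd.Index(gene_names, name="gene"),
    )
    truth = SyntheticTruth(cells=cell_meta, genes=gene_meta)
    matrix = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_names=list(gene_names),
        barcodes=list(barcodes),
        is_mito=is_mito.copy(),
        cell_meta=cell_meta[["tissue", "condition"]].copy(),
    )
    return matrix, truth


def _random_cdr3b(rng: np.random.Generator, used: set[str]) -> str:
    """A fresh CDR3beta amino-acid string (C...F, length 11-17)."""
    while True:
        length = int(rng.integers(11, 18))
        core = "".join(rng.choice(list(_AA), size=length - 2))
        cdr3 = "C" + core + "F"
        if cdr3 not in used:
            used.add(cdr3)
            return cdr3


def simulate_tcr(truth: SyntheticTruth, params: SimParams) -> list:
    """Draw paired-chain contigs for every cell in ``truth``.

    Every cell receives one invariant alpha contig and one beta contig whose
    clonotype is drawn from its subpopulation's Dirichlet-multinomial clone
    pool. Clones named in ``shared_clone_spec`` are injected into both
    subpopulations' pools and guaranteed at least one cell on each side (and
    are exempt from quality-flag noise), so engineered overlap is exact.
    A ``fraction_nonproductive`` / ``fraction_low_confidence`` of the
    remaining contigs is flagged accordingly. Deterministic given the seed.

    Updates ``truth`` in place (clonotype_id, clone tables) and returns the
    contig records.
    """
    from .repertoire import ContigRecord

    params.validate()
    rng = params.streams()["tcr"]
    used_cdr3: set[str] = set()

    # Per-subpopulation clone pools: list of clonotype ids; global key table.
    keys: dict[str, tuple[str, str, str, str, str, str]] = {}
    pools: dict[str, list[str]] = {}
    counter = 0

    def new_clone() -> str:
        nonlocal counter
        v = str(rng.choice(_V_BETA))
        j = str(rng.choice(_J_BETA))
        cdr3 = _random_cdr3b(rng, used_cdr3)
        cid = f"CL{counter:04d}"
        counter += 1
        keys[cid] = (*INVARIANT_ALPHA, v, j, cdr3)
        return cid

    for name in params.subpop_names:
        pools[name] = [new_clone() for _ in range(params.n_clones_per_subpop)]

    shared_ids: dict[str, tuple[str, str]] = {}
    for a, b, n in params.shared_clone_spec:
        for _ in range(n):
            cid = new_clone()
            pools[a].append(cid)
            pools[b].append(cid)
            shared_ids[cid] = (a, b)

    cells = truth.cells
    clone_of = pd.Series("", index=cells.index, dtype=object)
    for name in params.subpop_names:
        members = cells.index[cells["subpop"] == name]
        if len(members) == 0:
            continue
        pool = pools[name]
        freq = rng.dirichlet(np.full(len(pool), params.clone_dirichlet_alpha))
        clone_of[members] = rng.choice(pool, size=len(members), p=freq)

    # Guarantee each engineered shared clone is realized on both sides.
    for cid, (a, b) in shared_ids.items():
        for name in (a, b):
            members = cells.index[cells["subpop"] == name]
            if len(members) == 0:
                continue
            if not (clone_of[members] == cid).any():
                assigned = clone_of[members]
                # Reassign a cell from the most expanded non-shared clone.
                candidates = assigned[~assigned.isin(list(shared_ids))]
                pick = (
                    candidates.index[0] if len(candidates) else members[0]
                )
                clone_of[pick] = cid

    cells["clonotype_id"] = clone_of

    records: list[ContigRecord] = []
    protected: list[bool] = []  # shared-clone cells keep clean flags
    for barcode, cid in clone_of.items():
        va, ja, ca, vb, jb, cb = keys[cid]
        is_shared = cid in shared_ids
        for chain, v, j, cdr3 in (("TRA", va, ja, ca), ("TRB", vb, jb, cb)):
            records.append(
                ContigRecord(
                    barcode=barcode,
                    chain=chain,
                    v_gene=v,
                    j_gene=j,
                    cdr3=cdr3,
                    productive=True,
                    high_confidence=True,
                    umis=int(rng.integers(2, 50)),
                )
            )
            protected.append(is_shared)

    protected_arr = np.asarray(protected)
    open_idx = np.flatnonzero(~protected_arr)
    n_bad = int(round(params.fraction_nonproductive * len(records)))
    n_low = int(round(params.fraction_low_confidence * len(records)))
    n_bad = min(n_bad, open_idx.size)
    bad = rng.choice(open_idx, size=n_bad, replace=False) if n_bad else []
    for i in bad:
        records[i].productive = False
    n_low = min(n_low, open_idx.size)
    low = rng.choice(open_idx, size=n_low, replace=False) if n_low else []
    for i in low:
        records[i].high_confidence = False

    counts = (
        cells.groupby(["subpop", "clonotype_id"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    truth.clone_tables = counts
    truth.clonotype_keys = pd.DataFrame(
        [(cid, *key) for cid, key in sorted(keys.items())],
        columns=["clonotype_id", "v_alpha", "j_alpha", "cdr3_alpha",
                 "v_beta", "j_beta", "cdr3_beta"],
    ).set_index("clonotype_id")
    return records


def write_synthetic_dataset(outdir, matrix, truth: SyntheticTruth, contigs) -> dict:
    """Persist one simulated experiment as the standard text triplet + tables.

    Returns a manifest mapping logical names to file paths.
    """
    from pathlib import Path

    from .io_formats import write_contigs_csv, write_counts_mtx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = write_counts_mtx(outdir, matrix)
    meta_path = outdir / "cell_meta.tsv"
    matrix.cell_meta.to_csv(meta_path, sep="\t")
    manifest["cell_meta"] = str(meta_path)
    contig_path = outdir / "contigs.csv"
    write_contigs_csv(contig_path, contigs)
    manifest["contigs"] = str(contig_path)
    truth_cells = outdir / "truth_cells.tsv"
    truth.cells.to_csv(truth_cells, sep="\t")
    manifest["truth_cells"] = str(truth_cells)
    truth_genes = outdir / "truth_genes.tsv"
    truth.genes.to_csv(truth_genes, sep="\t")
    manifest["truth_genes"] = str(truth_genes)
    if truth.clone_tables is not None:
        p = outdir / "truth_clones.tsv"
        truth.clone_tables.to_csv(p, sep="\t", index=False)
        manifest["truth_clones"] = str(p)
    return manifest
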