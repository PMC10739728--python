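"""Readers/writers for the standard formats the pipeline touches, plus config.

Count matrices travel as a 10x-style MatrixMarket triplet (matrix.mtx,
features.tsv, barcodes.tsv; 1-based on disk, 0-based in memory), V(D)J contigs
as the ``filtered_contig_annotations.csv`` dialect, and everything else as
plain TSV/JSON.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Cell-by-gene integer UMI counts with identifiers and mito flags."""

    counts: sp.csr_matrix  # cells x genes
    gene_names: list[str]
    barcodes: list[str]
    is_mito: np.ndarray  # bool per gene
    cell_meta: pd.DataFrame | None = None  # index barcode; tissue, condition, ...

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def total_umis(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        meta = self.cell_meta.iloc[idx] if self.cell_meta is not None else None
        return CountMatrix(
            counts=self.counts[idx],
            gene_names=list(self.gene_names),
            barcodes=[self.barcodes[i] for i in idx],
            is_mito=self.is_mito.copy(),
            cell_meta=meta,
        )


@dataclass
class NormalizedMatrix:
    """log2 size-factor-normalized expression (dense, cells x genes)."""

    values: np.ndarray
    gene_names: list[str]
    barcodes: list[str]
    size_factors: np.ndarray
    pseudocount: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class PipelineConfig:
    """Fixed numbers of the analysis, with the published defaults.

    QC keeps cells with >= 1000 UMIs and <= 10% mitochondrial UMI fraction
    (exclusion rules are strict inequalities); HVGs are genes with FDR < 0.05
    for biological variability; clustering runs on the first 15 principal
    components at resolution 0.8; projection uses the k = 5 highest Pearson
    correlations.
    """

    min_umi: int = 1000
    max_mito_fraction: float = 0.10
    hvg_fdr: float = 0.05
    n_pcs: int = 15
    cluster_resolution: float = 0.8
    k_project: int = 5
    pseudocount: float = 1.0
    log_base: int = 2  # fixed
    de_correction: str = "bonferroni"  # or "bh"
    mito_prefix: str = "mt-"
    seed: int = 0
    # pipeline orchestration extras
    ref_tissue: str = "T0"
    start_cluster: int = 0
    end_clusters: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.min_umi < 0:
            raise ValueError("min_umi must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.k_project < 1:
            raise ValueError("k_project must be >= 1")
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.log_base != 2:
            raise ValueError("log_base is fixed at 2")
        if self.de_correction not in ("bonferroni", "bh"):
            raise ValueError("de_correction must be 'bonferroni' or 'bh'")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat key: value text file (YAML mapping)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config {path} is not a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "end_clusters" in data and data["end_clusters"] is not None:
            data["end_clusters"] = tuple(int(x) for x in data["end_clusters"])
        return cls(**data)

    def to_file(self, path) -> None:
        data = dataclasses.asdict(self)
        data["end_clusters"] = list(self.end_clusters)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# MTX triplet
# ---------------------------------------------------------------------------


def write_counts_mtx(outdir, matrix: CountMatrix) -> dict:
    """Write matrix.mtx (genes x cells, 1-based) + features.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx_path = outdir / "matrix.mtx"
    # 10x convention stores genes as rows.
    scipy.io.mmwrite(
        str(mtx_path), sp.coo_matrix(matrix.counts.T), field="integer"
    )
    feat_path = outdir / "features.tsv"
    pd.DataFrame({"gene": matrix.gene_names}).to_csv(
        feat_path, sep="\t", header=False, index=False
    )
    bc_path = outdir / "barcodes.tsv"
    pd.DataFrame({"barcode": matrix.barcodes}).to_csv(
        bc_path, sep="\t", header=False, index=False
    )
    return {
        "matrix": str(mtx_path),
        "features": str(feat_path),
        "barcodes": str(bc_path),
    }


def read_counts_mtx(path, mito_prefix: str = "mt-") -> CountMatrix:
    """Read a 10x-style triplet directory into a :class:`CountMatrix`.

    Mito flags come from a case-insensitive gene-name prefix match.
    Raises :class:`FormatError` on dimension mismatch, non-integer values, or
    duplicate barcodes.
    """
    path = Path(path)
    mtx_path = path / "matrix.mtx"
    feat_path = path / "features.tsv"
    bc_path = path / "barcodes.tsv"
    for p in (mtx_path, feat_path, bc_path):
        if not p.exists():
            raise FormatError(f"missing triplet file: {p}")
    mat = scipy.io.mmread(str(mtx_path))
    dense_vals = mat.tocoo().data
    if dense_vals.size and not np.allclose(dense_vals, np.round(dense_vals)):
        raise FormatError(f"{mtx_path}: non-integer count values")
    if dense_vals.size and dense_vals.min() < 0:
        raise FormatError(f"{mtx_path}: negative count values")
    counts = sp.csr_matrix(mat.T.astype(np.int64))  # cells x genes
    genes = pd.read_csv(feat_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
    if len(genes) != counts.shape[1]:
        raise FormatError(
            f"features.tsv has {len(genes)} genes but matrix has {counts.shape[1]}"
        )
    if len(barcodes) != counts.shape[0]:
        raise FormatError(
            f"barcodes.tsv has {len(barcodes)} cells but matrix has {counts.shape[0]}"
        )
    if len(set(barcodes)) != len(barcodes):
        raise FormatError("duplicate barcodes in barcodes.tsv")
    prefix = mito_prefix.lower()
    is_mito = np.array([g.lower().startswith(prefix) for g in genes])
    meta_path = path / "cell_meta.tsv"
    cell_meta = None
    if meta_path.exists():
        cell_meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        cell_meta = cell_meta.loc[barcodes]
    return CountMatrix(
        counts=counts,
        gene_names=genes,
        barcodes=barcodes,
        is_mito=is_mito,
        cell_meta=cell_meta,
    )


# ---------------------------------------------------------------------------
# Contig CSV (filtered_contig_annotations.csv dialect)
# ---------------------------------------------------------------------------

CONTIG_COLUMNS = [
    "barcode",
    "is_cell",
    "high_confidence",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "productive",
    "umis",
]


def _parse_bool(value) -> bool:
    # 10x emits "True"/"False"/"None"; anything but a true-ish token is False.
    return str(value).strip().lower() == "true"


def read_contigs_csv(path) -> list:
    """Parse a contig annotation CSV into :class:`ContigRecord` objects."""
    from .repertoire import ContigRecord

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ContigRecord(
                barcode=row.barcode,
                chain=row.chain,
                v_gene=row.v_gene,
                j_gene=row.j_gene,
                cdr3=row.cdr3,
                productive=_parse_bool(row.productive),
                high_confidence=_parse_bool(row.high_confidence),
                umis=int(float(row.umis)) if row.umis != "" else 0,
            )
        )
    return records


def write_contigs_csv(path, records) -> None:
    rows = [
        {
            "barcode": r.barcode,
            "is_cell": "True",
            "high_confidence": "True" if r.high_confidence else "False",
            "chain": r.chain,
            "v_gene": r.v_gene,
            "j_gene": r.j_gene,
            "cdr3": r.cdr3,
            "productive": "True" if r.productive else "False",
            "umis": r.umis,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CONTIG_COLUMNS).to_csv(path, index=False)
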