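"""Cell QC, size-factor normalization, and highly-variable-gene selection.

QC excludes cells with fewer than ``min_umi`` total UMIs or more than
``max_mito_fraction`` of UMIs on mitochondrial genes (strict inequalities on
the exclusion side). Counts are divided by per-cell size factors and log2
transformed with a pseudocount. HVGs are genes whose log-expression variance
exceeds a smooth mean-variance trend with BH FDR below ``hvg_fdr``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, NormalizedMatrix, PipelineConfig


class EmptyResultError(RuntimeError):
    """All cells were removed by QC."""


@dataclass
class QCReport:
    """Per-cell QC metrics and pass/fail decisions."""

    table: pd.DataFrame  # index barcode; total_umis, mito_fraction, kept, reason

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())


def filter_cells(counts: CountMatrix, config: PipelineConfig):
    """Apply the UMI and mitochondrial-fraction filters.

    Keeps cells with ``total >= min_umi`` and ``mito fraction <=
    max_mito_fraction`` (a cell at exactly 1000 UMIs or exactly 10.0% mito is
    kept). Returns the filtered matrix and a report covering every input cell.
    """
    total = counts.total_umis().astype(float)
    mito_total = np.asarray(
        counts.counts[:, np.flatnonzero(counts.is_mito)].sum(axis=1)
    ).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)

    low_umi = total < config.min_umi
    high_mito = mito_frac > config.max_mito_fraction
    kept = ~(low_umi | high_mito)
    reason = np.where(
        low_umi & high_mito,
        "low_umi;high_mito",
        np.where(low_umi, "low_umi", np.where(high_mito, "high_mito", "")),
    )
    report = QCReport(
        pd.DataFrame(
            {
                "total_umis": total.astype(int),
                "mito_fraction": mito_frac,
                "kept": kept,
                "reason": reason,
            },
            index=pd.Index(counts.barcodes, name="barcode"),
        )
    )
    if not kept.any():
        raise EmptyResultError("QC removed every cell")
    return counts.subset_cells(kept), report


def compute_size_factors(counts: CountMatrix, method: str = "library") -> np.ndarray:
    """Per-cell size factors with mean exactly 1.

    ``method="library"`` (default): library-size factors. ``method="deconvolution"``:
    pool-based estimator — cells are ordered by library size on a ring,
    overlapping pools are compared with the average pseudo-cell, and per-cell
    factors are recovered by non-negative least squares. On data without
    strong composition effects the two coincide.
    """
    total = counts.total_umis().astype(float)
    if (total <= 0).any():
        raise ValueError("zero-total cell encountered; run QC first")
    lib = total / total.mean()
    if method == "library":
        return lib
    if method != "deconvolution":
        raise ValueError(f"unknown size-factor method {method!r}")

    x = np.asarray(counts.counts.todense(), dtype=float)
    n = x.shape[0]
    ref = x.mean(axis=0)
    keep = ref > 0
    xk, refk = x[:, keep], ref[keep]

    order = np.argsort(total, kind="stable")
    ring = np.concatenate([order, order])
    sizes = [s for s in (21, 41, 61, 81, 101) if s <= n] or [max(2, n // 2)]
    rows, rhs = [], []
    for size in sizes:
        for start in range(n):
            pool = ring[start : start + size]
            pooled = xk[pool].sum(axis=0)
            ratios = pooled / refk
            row = np.zeros(n)
            row[pool] = 1.0
            rows.append(row)
            rhs.append(np.median(ratios))
    # Low-weight library-size prior fixes scale and guards rank deficiency;
    # it is exactly consistent with the pool equations on proportional data.
    w = 0.1
    rows.append(w * np.eye(n))
    rhs.append(w * lib)
    a = np.vstack([np.atleast_2d(r) for r in rows])
    b = np.concatenate([np.atleast_1d(r) for r in rhs])
    theta, _ = scipy.optimize.nnls(a, b)
    if (theta <= 0).any():
        # NNLS pinned a factor at zero; fall back to its library-size value.
        theta = np.where(theta <= 0, lib, theta)
    return theta / theta.mean()


def lognormalize(
    counts: CountMatrix, size_factors: np.ndarray, config: PipelineConfig
) -> NormalizedMatrix:
    """``value = log2(count / size_factor + pseudocount)``."""
    sf = np.asarray(size_factors, dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be strictly positive")
    if sf.shape[0] != counts.n_cells:
        raise ValueError("size-factor vector length mismatch")
    dense = np.asarray(counts.counts.todense(), dtype=float)
    values = np.log2(dense / sf[:, None] + config.pseudocount)
    return NormalizedMatrix(
        values=values,
        gene_names=list(counts.gene_names),
        barcodes=list(counts.barcodes),
        size_factors=sf,
        pseudocount=config.pseudocount,
    )


@dataclass
class HVGTable:
    """Per-gene variance decomposition and selection flags."""

    table: pd.DataFrame  # index gene; mean, total_var, trend_var, bio_var,
    #                      pvalue, fdr, selected

    @property
    def selected_genes(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()


def select_hvgs(norm: NormalizedMatrix, config: PipelineConfig) -> HVGTable:
    """Decompose per-gene variance into trend + biological components.

    A lowess trend (span 0.3) of total variance against mean expression
    models the technical mean-variance relation; the biological component is
    the residual. Significance is a one-sided z-test of the residual against
    a robust (MAD-based) estimate of the residual spread, with BH FDR across
    genes. Selected genes have ``FDR < hvg_fdr`` and positive biological
    variance.
    """
    x = norm.values
    n_genes = x.shape[1]
    if n_genes < 20:
        raise ValueError("need at least 20 genes to fit a variance trend")
    mean = x.mean(axis=0)
    if np.allclose(mean, mean[0]):
        raise ValueError("degenerate trend fit: all gene means equal")
    total_var = x.var(axis=0, ddof=1)

    trend = lowess(
        total_var, mean, frac=0.3, it=3, return_sorted=False
    )
    trend = np.maximum(trend, 0.0)
    bio = total_var - trend
    # Robust spread so strongly variable genes do not mask themselves.
    sd = 1.4826 * np.median(np.abs(bio - np.median(bio)))
    if sd == 0:
        raise ValueError("degenerate trend fit: zero residual spread")
    z = bio / sd
    pvalue = scipy.stats.norm.sf(z)
    _, fdr, _, _ = multipletests(pvalue, method="fdr_bh")
    selected = (fdr < config.hvg_fdr) & (bio > 0)
    return HVGTable(
        pd.DataFrame(
            {
                "mean": mean,
                "total_var": total_var,
                "trend_var": trend,
                "bio_var": bio,
                "pvalue": pvalue,
                "fdr": fdr,
                "selected": selected,
            },
            index=pd.Index(norm.gene_names, name="gene"),
        )
    )
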