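"""Cluster markers, condition-wise differential expression, and module scores.

Marker detection is a one-vs-rest two-sided Wilcoxon rank-sum per gene.
Small groups (both sides <= 8 cells) use exact enumeration of rank
assignments; larger groups use the normal approximation with mid-rank tie
correction and continuity correction. Condition DE uses Bonferroni
adjustment by default; marker tables use Benjamini-Hochberg within cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_formats import NormalizedMatrix, PipelineConfig

EXACT_MAX_N = 8


@dataclass
class MarkerTable:
    table: pd.DataFrame  # cluster, gene, mean_in, mean_out, log2fc, pvalue, padj


def ranksum_p_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by exhaustive enumeration (mid-ranks under ties).

    ``p = P(|W - E[W]| >= |W_obs - E[W]|)`` over all C(n1+n2, n1) assignments
    of the pooled mid-ranks to the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = len(x), len(x) + len(y)
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = total = 0
    for combo in combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p; exact below ``EXACT_MAX_N`` per group."""
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return ranksum_p_exact(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(
        scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def _ranksum_p_matrix(xin: np.ndarray, xout: np.ndarray) -> np.ndarray:
    """Vectorized per-gene p-values for one group split (columns = genes)."""
    n1, n2 = xin.shape[0], xout.shape[0]
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        return np.array(
            [ranksum_p_exact(xin[:, g], xout[:, g]) for g in range(xin.shape[1])]
        )
    pooled = np.vstack([xin, xout])
    flat = np.ptp(pooled, axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.mannwhitneyu(
            xin,
            xout,
            alternative="two-sided",
            method="asymptotic",
            use_continuity=True,
            axis=0,
        )
    p = np.asarray(res.pvalue, dtype=float)
    p[flat] = 1.0
    return p


def _log2fc(xin: np.ndarray, xout: np.ndarray, pseudocount: float) -> np.ndarray:
    # De-logged group means plus pseudocount (single-cell convention).
    m_in = np.maximum(np.exp2(xin).mean(axis=0) - pseudocount, 0.0)
    m_out = np.maximum(np.exp2(xout).mean(axis=0) - pseudocount, 0.0)
    return np.log2(m_in + pseudocount) - np.log2(m_out + pseudocount)


def find_markers(norm: NormalizedMatrix, labels: np.ndarray) -> MarkerTable:
    """One-vs-rest rank-sum markers per cluster, BH-adjusted within cluster.

    Clusters with fewer than 3 cells are skipped with a warning. Rows are
    sorted by adjusted p, then by decreasing |log2FC|.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for marker detection")
    frames = []
    for c in clusters:
        mask = labels == c
        if mask.sum() < 3:
            warnings.warn(f"cluster {c} has < 3 cells; skipped", UserWarning)
            continue
        xin, xout = norm.values[mask], norm.values[~mask]
        p = _ranksum_p_matrix(xin, xout)
        _, padj, _, _ = multipletests(p, method="fdr_bh")
        df = pd.DataFrame(
            {
                "cluster": c,
                "gene": norm.gene_names,
                "mean_in": xin.mean(axis=0),
                "mean_out": xout.mean(axis=0),
                "log2fc": _log2fc(xin, xout, norm.pseudocount),
                "pvalue": p,
                "padj": padj,
            }
        )
        df = df.sort_values(
            ["padj", "log2fc"],
            key=lambda s: s if s.name == "padj" else -s.abs(),
            kind="stable",
        ).reset_index(drop=True)
        frames.append(df)
    return MarkerTable(pd.concat(frames, ignore_index=True))


def condition_de(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    condition: np.ndarray,
    config: PipelineConfig,
) -> MarkerTable:
    """Within-cluster two-condition rank-sum DE with Bonferroni adjustment.

    ``adj = min(1, m * p)`` with m = number of genes tested (per cluster);
    ``config.de_correction = "bh"`` switches to Benjamini-Hochberg.
    """
    labels = np.asarray(labels)
    condition = np.asarray(condition)
    conds = np.unique(condition)
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {list(conds)}")
    frames = []
    for c in np.unique(labels):
        in_cluster = labels == c
        a = in_cluster & (condition == conds[0])
        b = in_cluster & (condition == conds[1])
        if a.sum() < 3 or b.sum() < 3:
            warnings.warn(
                f"cluster {c}: condition stratum below 3 cells; skipped", UserWarning
            )
            continue
        xa, xb = norm.values[a], norm.values[b]
        p = _ranksum_p_matrix(xa, xb)
        if config.de_correction == "bonferroni":
            padj = np.minimum(1.0, p * p.size)
        else:
            _, padj, _, _ = multipletests(p, method="fdr_bh")
        frames.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "gene": norm.gene_names,
                    "mean_in": xa.mean(axis=0),
                    "mean_out": xb.mean(axis=0),
                    "log2fc": _log2fc(xa, xb, norm.pseudocount),
                    "pvalue": p,
                    "padj": padj,
                }
            )
        )
    if not frames:
        raise ValueError("no cluster had both conditions with >= 3 cells")
    return MarkerTable(pd.concat(frames, ignore_index=True))


def module_score(
    norm: NormalizedMatrix,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Expression-bin-matched signature score per cell.

    Genes are binned by average expression; each set gene is compared with
    control genes from its own bin excluding itself (the whole remaining bin
    when it holds <= ``n_ctrl`` genes, else a seeded sample). The score is
    the mean over set genes of (gene value - mean control value); within-bin
    deviations sum to zero, so a set equal to all genes scores exactly zero
    in every cell.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    name_to_idx = {g: i for i, g in enumerate(norm.gene_names)}
    missing = [g for g in gene_set if g not in name_to_idx]
    if missing:
        raise ValueError(f"gene set members absent from matrix: {missing[:5]}")
    n_genes = len(norm.gene_names)
    if n_genes < n_bins:
        raise ValueError(f"need >= n_bins={n_bins} genes, got {n_genes}")

    avg = norm.values.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bins = np.array_split(order, n_bins)
    bin_of = np.empty(n_genes, dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b

    rng = np.random.default_rng(seed)
    x = norm.values
    n_cells = x.shape[0]
    diff_sum = np.zeros(n_cells)
    for g in gene_set:
        gi = name_to_idx[g]
        members = bins[bin_of[gi]]
        members = members[members != gi]
        if members.size == 0:
            raise ValueError(f"gene {g!r} is alone in its expression bin")
        if members.size <= n_ctrl:
            ctrl = members
        else:
            ctrl = rng.choice(members, size=n_ctrl, replace=False)
        diff_sum += x[:, gi] - x[:, ctrl].mean(axis=1)
    return diff_sum / len(gene_set)
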