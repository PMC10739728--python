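"""Paired-chain TCR repertoire analytics.

Contigs are restricted to productive, high-confidence assemblies; cells
sharing identical V/J composition and CDR3 sequences on both chains form a
clonotype. Per-group statistics: normalized Shannon diversity (Pielou
evenness, entropy over cells-per-clonotype divided by ln richness),
pairwise clonotype overlap (shared counts + Jaccard) with shared-clone
composition, and CDR3beta spectratypes (length histogram, modal length, and
a positional amino-acid frequency matrix at the modal length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

ClonotypeKey = tuple[str, str, str, str, str, str]  # Va, Ja, CDR3a, Vb, Jb, CDR3b


@dataclass
class ContigRecord:
    barcode: str
    chain: str  # "TRA" or "TRB"
    v_gene: str
    j_gene: str
    cdr3: str
    productive: bool
    high_confidence: bool
    umis: int


@dataclass
class ClonotypeTable:
    """Per-cell paired-chain clonotype assignment."""

    cells: pd.DataFrame  # index barcode; clonotype_id (or "") + key columns
    keys: pd.DataFrame  # index clonotype_id; the six key fields

    def assigned(self) -> pd.DataFrame:
        return self.cells[self.cells["clonotype_id"] != ""]


def filter_contigs(records: list[ContigRecord]) -> list[ContigRecord]:
    """Keep contigs that are both productive and high-confidence."""
    return [r for r in records if r.productive and r.high_confidence]


def _best_contig(contigs: list[ContigRecord]) -> ContigRecord:
    # Highest UMI count; ties by lexicographically smallest CDR3.
    return min(contigs, key=lambda r: (-r.umis, r.cdr3, r.v_gene, r.j_gene))


def call_clonotypes(records: list[ContigRecord], cell_barcodes) -> ClonotypeTable:
    """Assign each cell its paired-chain clonotype.

    Per cell and chain the highest-UMI contig is selected (ties broken by
    smallest CDR3); cells lacking either chain stay unassigned. Records with
    barcodes outside ``cell_barcodes`` are dropped with a warning.
    Clonotype ids are assigned by key equality, numbered in order of first
    appearance over the cell list.
    """
    cell_barcodes = list(cell_barcodes)
    known = set(cell_barcodes)
    by_cell: dict[str, dict[str, list[ContigRecord]]] = {}
    dropped = 0
    for r in records:
        if r.barcode not in known:
            dropped += 1
            continue
        by_cell.setdefault(r.barcode, {}).setdefault(r.chain, []).append(r)
    if dropped:
        warnings.warn(
            f"{dropped} contig(s) with unknown barcodes dropped", UserWarning
        )

    key_to_id: dict[ClonotypeKey, str] = {}
    rows = []
    for bc in cell_barcodes:
        chains = by_cell.get(bc, {})
        key: ClonotypeKey | None = None
        if "TRA" in chains and "TRB" in chains:
            a = _best_contig(chains["TRA"])
            b = _best_contig(chains["TRB"])
            key = (a.v_gene, a.j_gene, a.cdr3, b.v_gene, b.j_gene, b.cdr3)
        if key is None:
            rows.append((bc, "", "", "", "", "", "", ""))
            continue
        if key not in key_to_id:
            key_to_id[key] = f"CT{len(key_to_id):04d}"
        rows.append((bc, key_to_id[key], *key))
    cols = ["barcode", "clonotype_id", "v_alpha", "j_alpha", "cdr3_alpha",
            "v_beta", "j_beta", "cdr3_beta"]
    cells = pd.DataFrame(rows, columns=cols).set_index("barcode")
    keys = pd.DataFrame(
        [(cid, *key) for key, cid in key_to_id.items()],
        columns=["clonotype_id"] + cols[2:],
    ).set_index("clonotype_id")
    return ClonotypeTable(cells=cells, keys=keys)


def diversity_normalized_shannon(clone_counts) -> float:
    """Pielou evenness: ``(-sum p_i ln p_i) / ln(S)``; one clonotype -> 0."""
    counts = np.asarray(clone_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty clone-count vector")
    if (counts <= 0).any():
        raise ValueError("clone counts must be positive")
    if counts.size == 1:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(counts.size))


def group_diversity(table: ClonotypeTable, groups) -> pd.DataFrame:
    """Normalized Shannon diversity and richness per group of cells."""
    groups = pd.Series(np.asarray(groups), index=table.cells.index)
    rows = []
    for g in pd.unique(groups):
        members = table.cells[(groups == g) & (table.cells["clonotype_id"] != "")]
        if members.empty:
            warnings.warn(f"group {g!r}: no assigned cells; skipped", UserWarning)
            continue
        counts = members["clonotype_id"].value_counts().to_numpy()
        rows.append(
            {
                "group": g,
                "n_cells": len(members),
                "richness": counts.size,
                "normalized_shannon": diversity_normalized_shannon(counts),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def clonotype_overlap(table: ClonotypeTable, groups):
    """Pairwise shared-clonotype counts and Jaccard indices across groups.

    Returns ``(shared, jaccard, composition)``: two symmetric DataFrames
    (Jaccard has unit diagonal) and a long table giving, for every clonotype
    present in >= 2 groups, its per-group cell counts.
    """
    groups = pd.Series(np.asarray(groups), index=table.cells.index)
    sets: dict[object, set[str]] = {}
    counts: dict[object, pd.Series] = {}
    for g in pd.unique(groups):
        members = table.cells[(groups == g) & (table.cells["clonotype_id"] != "")]
        if members.empty:
            warnings.warn(f"group {g!r}: no assigned cells; excluded", UserWarning)
            continue
        sets[g] = set(members["clonotype_id"])
        counts[g] = members["clonotype_id"].value_counts()
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 groups with assigned cells")
    n = len(names)
    shared = np.zeros((n, n), dtype=int)
    jaccard = np.zeros((n, n))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            shared[i, j] = inter
            jaccard[i, j] = inter / union if union else 0.0
    shared_df = pd.DataFrame(shared, index=names, columns=names)
    jaccard_df = pd.DataFrame(jaccard, index=names, columns=names)

    rows = []
    all_ids = sorted(set().union(*sets.values()))
    for cid in all_ids:
        present = [g for g in names if cid in sets[g]]
        if len(present) < 2:
            continue
        for g in present:
            rows.append(
                {"clonotype_id": cid, "group": g, "n_cells": int(counts[g][cid])}
            )
    composition = pd.DataFrame(rows, columns=["clonotype_id", "group", "n_cells"])
    return shared_df, jaccard_df, composition


def cdr3_spectratype(table: ClonotypeTable, barcodes):
    """CDR3beta spectratype for a group of cells.

    Returns ``(histogram, modal_length, frequency_matrix)``: a length ->
    cell-count Series, the most prevalent CDR3beta length (ties to the
    shorter), and a 20 x L amino-acid frequency matrix over cells whose
    CDR3beta has the modal length (columns sum to 1).
    """
    cells = table.cells.loc[
        [bc for bc in barcodes if bc in table.cells.index]
    ]
    cells = cells[cells["clonotype_id"] != ""]
    if cells.empty:
        raise ValueError("no assigned cells in group")
    lengths = cells["cdr3_beta"].str.len()
    hist = lengths.value_counts().sort_index()
    top = hist.max()
    modal = int(min(hist.index[hist == top]))
    seqs = cells.loc[lengths == modal, "cdr3_beta"]
    freq = np.zeros((len(AA_ALPHABET), modal))
    aa_idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    for s in seqs:
        for pos, aa in enumerate(s):
            if aa in aa_idx:
                freq[aa_idx[aa], pos] += 1
    colsum = freq.sum(axis=0)
    colsum[colsum == 0] = 1.0
    freq = freq / colsum
    freq_df = pd.DataFrame(
        freq,
        index=pd.Index(list(AA_ALPHABET), name="aa"),
        columns=[f"pos{i + 1}" for i in range(modal)],
    )
    return hist, modal, freq_df
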