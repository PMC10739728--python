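"""Rank-sum marker tests (exact + asymptotic), condition DE, module scores."""

from itertools import combinations

import numpy as np
import pytest
import scipy.stats

from conftest import make_norm
from inktmap.io_formats import PipelineConfig
from inktmap.markers import (
    condition_de,
    find_markers,
    module_score,
    ranksum_p,
    ranksum_p_exact,
)


def enumeration_oracle(x, y):
    """Independent exhaustive two-sided rank-sum p (own midranks, no scipy)."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2.0
    obs = abs(sum(ranks[:n1]) - mu)
    hits = total = 0
    for combo in combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[c] for c in combo) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def test_most_extreme_three_vs_three_gives_point_one():
    assert ranksum_p_exact([1, 1, 1], [0, 0, 0]) == pytest.approx(0.1)


@pytest.mark.parametrize("seed", range(6))
def test_exact_p_matches_independent_enumeration(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(3, 9, size=2)
    x = rng.integers(0, 4, size=n1).astype(float)  # heavy ties
    y = rng.integers(0, 4, size=n2).astype(float)
    assert ranksum_p_exact(x, y) == pytest.approx(enumeration_oracle(x, y), abs=1e-12)


@pytest.mark.parametrize("seed", range(4))
def test_exact_p_matches_scipy_exact_without_ties(seed):
    rng = np.random.default_rng(100 + seed)
    x = rng.normal(size=6)
    y = rng.normal(size=7)
    expected = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact"
    ).pvalue
    assert ranksum_p(x, y) == pytest.approx(expected, abs=1e-12)


def test_find_markers_symmetry_and_null_fc():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(40, 30))
    values[:20, :5] += 2.0  # cluster 0 markers
    norm = make_norm(values)
    labels = np.array([0] * 20 + [1] * 20)
    table = find_markers(norm, labels).table
    t0 = table[table["cluster"] == 0].set_index("gene")
    t1 = table[table["cluster"] == 1].set_index("gene")
    for g in norm.gene_names:
        assert t0.loc[g, "pvalue"] == pytest.approx(t1.loc[g, "pvalue"], abs=1e-10)
        assert t0.loc[g, "log2fc"] == pytest.approx(-t1.loc[g, "log2fc"], abs=1e-10)
    # Identical in/out distribution: a constant gene has log2FC exactly 0.
    values2 = values.copy()
    values2[:, 9] = 1.0
    table2 = find_markers(make_norm(values2), labels).table
    assert table2.set_index(["cluster", "gene"]).loc[(0, "G9"), "log2fc"] == 0.0
    # The true markers surface at the top of cluster 0's list.
    assert set(t0.sort_values(["padj"]).head(5).index) == {f"G{i}" for i in range(5)}


def test_tiny_cluster_is_skipped_with_warning():
    rng = np.random.default_rng(1)
    norm = make_norm(rng.normal(size=(23, 10)))
    labels = np.array([0] * 20 + [1] * 3 + [2] * 0)
    labels[-2:] = 2  # cluster 1 left with 1 cell
    with pytest.warns(UserWarning, match="skipped"):
        table = find_markers(norm, labels).table
    assert 1 not in set(table["cluster"])


def test_condition_de_bonferroni_formula():
    rng = np.random.default_rng(2)
    m_genes = 40
    values = rng.normal(size=(60, m_genes))
    norm = make_norm(values)
    labels = np.zeros(60, dtype=int)
    condition = np.array(["NCD"] * 30 + ["HFD"] * 30)
    table = condition_de(norm, labels, condition, PipelineConfig()).table
    np.testing.assert_allclose(
        table["padj"], np.minimum(1.0, table["pvalue"] * m_genes)
    )
    assert (table["padj"] >= table["pvalue"] - 1e-12).all()
    assert (table["padj"] <= 1.0).all()


def test_condition_de_null_controls_false_positives():
    rng = np.random.default_rng(3)
    values = rng.normal(size=(200, 1000))
    norm = make_norm(values)
    labels = np.zeros(200, dtype=int)
    condition = rng.choice(["NCD", "HFD"], size=200)
    table = condition_de(norm, labels, condition, PipelineConfig()).table
    assert (table["padj"] < 0.05).mean() <= 0.05


def test_module_score_of_all_genes_is_exactly_zero():
    rng = np.random.default_rng(4)
    norm = make_norm(rng.normal(size=(30, 60)))
    scores = module_score(norm, list(norm.gene_names), n_bins=10, n_ctrl=100, seed=0)
    np.testing.assert_allclose(scores, 0.0, atol=1e-12)


def test_module_score_detects_engineered_shift():
    # Shift a small cell subset so the gene-average bins stay unshifted.
    rng = np.random.default_rng(5)
    n_cells, n_genes = 1000, 500
    values = rng.normal(size=(n_cells, n_genes))
    gene_set = [f"G{i}" for i in range(0, 500, 20)]  # spread across bins
    shifted = np.arange(10)
    set_idx = [int(g[1:]) for g in gene_set]
    values[np.ix_(shifted, set_idx)] += 2.0
    norm = make_norm(values)
    scores = module_score(norm, gene_set, seed=0)
    assert scores[shifted].mean() == pytest.approx(2.0, abs=0.2)
    assert scores[shifted].mean() > scores[10:].mean() + 1.5


def test_module_score_deterministic_and_validates_input():
    rng = np.random.default_rng(6)
    norm = make_norm(rng.normal(size=(20, 100)))
    s1 = module_score(norm, ["G1", "G5"], seed=3)
    s2 = module_score(norm, ["G1", "G5"], seed=3)
    np.testing.assert_array_equal(s1, s2)
    with pytest.raises(ValueError):
        module_score(norm, [], seed=0)
    with pytest.raises(ValueError):
        module_score(norm, ["NOPE"], seed=0)
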