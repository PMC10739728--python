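"""Correlation-kNN projection against a brute-force oracle; mapping ratios."""

import numpy as np
import pytest

from conftest import hvg_all, make_norm
from inktmap.cluster_embed import Embedding
from inktmap.experiments import projection_bruteforce_oracle
from inktmap.io_formats import PipelineConfig
from inktmap.projection import mapping_ratio, project_cells


def ref_embedding(values, umap, labels):
    n = values.shape[0]
    return Embedding(
        barcodes=[f"R{i}" for i in range(n)],
        pcs=values[:, :2].copy(),
        umap=np.asarray(umap, dtype=float),
        labels=np.asarray(labels),
    )


def test_identical_query_projects_onto_its_reference_twin():
    rng = np.random.default_rng(0)
    ref_vals = rng.normal(size=(10, 20))
    umap = rng.normal(size=(10, 2))
    labels = np.arange(10) % 3
    ref = make_norm(ref_vals)
    query = make_norm(ref_vals[4:5], barcodes=["Q0"])
    cfg = PipelineConfig(k_project=1)
    res = project_cells(ref, ref_embedding(ref_vals, umap, labels), hvg_all(ref.gene_names), query, cfg)
    assert res.neighbor_indices[0, 0] == 4
    np.testing.assert_allclose(res.coordinates[0], umap[4])
    assert res.assigned_label[0] == labels[4]


def test_two_equal_neighbors_average_their_coordinates():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    ref_vals = np.vstack([base, base, -base])
    umap = np.array([[0.0, 0.0], [2.0, 2.0], [9.0, 9.0]])
    ref = make_norm(ref_vals)
    query = make_norm(base[None, :], barcodes=["Q0"])
    cfg = PipelineConfig(k_project=2)
    res = project_cells(
        ref, ref_embedding(ref_vals, umap, [0, 0, 1]), hvg_all(ref.gene_names), query, cfg
    )
    assert set(res.neighbor_indices[0]) == {0, 1}
    np.testing.assert_allclose(res.coordinates[0], [1.0, 1.0])


@pytest.mark.parametrize("seed", [0, 1])
def test_neighbors_match_bruteforce_pearson_oracle(seed):
    rng = np.random.default_rng(seed)
    ref_vals = rng.normal(size=(30, 25))
    q_vals = rng.normal(size=(10, 25))
    umap = rng.normal(size=(30, 2))
    labels = rng.integers(0, 4, size=30)
    cfg = PipelineConfig(k_project=5)
    res = project_cells(
        make_norm(ref_vals),
        ref_embedding(ref_vals, umap, labels),
        hvg_all([f"G{i}" for i in range(25)]),
        make_norm(q_vals, barcodes=[f"Q{i}" for i in range(10)]),
        cfg,
    )
    nn, corr, coords = projection_bruteforce_oracle(ref_vals, umap, q_vals, k=5)
    np.testing.assert_array_equal(res.neighbor_indices, nn)
    np.testing.assert_allclose(res.neighbor_correlations, corr, atol=1e-10)
    np.testing.assert_allclose(res.coordinates, coords, atol=1e-10)


def test_projection_invariant_to_affine_query_transform():
    rng = np.random.default_rng(2)
    ref_vals = rng.normal(size=(20, 15))
    q_vals = rng.normal(size=(6, 15))
    umap = rng.normal(size=(20, 2))
    labels = rng.integers(0, 3, size=20)
    cfg = PipelineConfig(k_project=3)
    args = (
        make_norm(ref_vals),
        ref_embedding(ref_vals, umap, labels),
        hvg_all([f"G{i}" for i in range(15)]),
    )
    r1 = project_cells(*args, make_norm(q_vals), cfg)
    r2 = project_cells(*args, make_norm(3.0 + 2.5 * q_vals), cfg)
    np.testing.assert_array_equal(r1.neighbor_indices, r2.neighbor_indices)
    np.testing.assert_allclose(r1.coordinates, r2.coordinates, atol=1e-10)
    assert (np.abs(r1.neighbor_correlations) <= 1 + 1e-12).all()


def test_zero_variance_query_is_unmappable_and_excluded_from_ratios():
    rng = np.random.default_rng(3)
    ref_vals = rng.normal(size=(10, 12))
    q_vals = rng.normal(size=(3, 12))
    q_vals[1] = 7.0  # flat cell
    cfg = PipelineConfig(k_project=2)
    with pytest.warns(UserWarning, match="unmappable"):
        res = project_cells(
            make_norm(ref_vals),
            ref_embedding(ref_vals, rng.normal(size=(10, 2)), np.zeros(10, dtype=int)),
            hvg_all([f"G{i}" for i in range(12)]),
            make_norm(q_vals, barcodes=["Q0", "Q1", "Q2"]),
            cfg,
        )
    assert res.mappable.tolist() == [True, False, True]
    assert res.assigned_label[1] == -1
    ratios = mapping_ratio(res, ["g", "g", "g"])
    assert ratios.loc["g"].sum() == pytest.approx(1.0)


def test_mapping_ratio_fractions():
    res_labels = np.array([0] * 6 + [2] * 4)
    from inktmap.projection import ProjectionResult

    res = ProjectionResult(
        barcodes=[f"Q{i}" for i in range(10)],
        neighbor_indices=np.zeros((10, 1), dtype=int),
        neighbor_correlations=np.ones((10, 1)),
        coordinates=np.zeros((10, 2)),
        assigned_label=res_labels,
        mappable=np.ones(10, dtype=bool),
        reference_labels=np.array([0, 1, 2]),
        shared_genes=["G0"],
        coverage=1.0,
    )
    ratios = mapping_ratio(res, ["all"] * 10)
    assert ratios.loc["all", "cluster0"] == pytest.approx(0.6)
    assert ratios.loc["all", "cluster1"] == pytest.approx(0.0)
    assert ratios.loc["all", "cluster2"] == pytest.approx(0.4)
    ratios2 = mapping_ratio(res, ["a"] * 10)
    assert ratios2.loc["a"].sum() == pytest.approx(1.0)


def test_low_gene_coverage_is_rejected():
    rng = np.random.default_rng(4)
    ref_vals = rng.normal(size=(8, 10))
    ref = make_norm(ref_vals)
    query = make_norm(rng.normal(size=(2, 3)), gene_names=["G0", "G1", "G2"],
                      barcodes=["Q0", "Q1"])
    with pytest.raises(ValueError, match="coverage|50%"):
        project_cells(
            ref,
            ref_embedding(ref_vals, rng.normal(size=(8, 2)), np.zeros(8, dtype=int)),
            hvg_all(ref.gene_names),
            query,
            PipelineConfig(k_project=2),
        )
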