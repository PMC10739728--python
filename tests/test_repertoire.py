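"""Clonotype calling, diversity, overlap, and spectratype analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inktmap.repertoire import (
    ClonotypeTable,
    ContigRecord,
    call_clonotypes,
    cdr3_spectratype,
    clonotype_overlap,
    diversity_normalized_shannon,
    filter_contigs,
)


def contig(bc, chain="TRB", v="TRBV13-1", j="TRBJ2-1", cdr3="CASSF",
           productive=True, hc=True, umis=5):
    return ContigRecord(bc, chain, v, j, cdr3, productive, hc, umis)


def paired(bc, cdr3b, v_b="TRBV13-1", j_b="TRBJ2-1", umis=5):
    return [
        contig(bc, "TRA", "TRAV11", "TRAJ18", "CVVGDRGSALGRLHF", umis=umis),
        contig(bc, "TRB", v_b, j_b, cdr3b, umis=umis),
    ]


def table_from(cells: dict[str, str]) -> ClonotypeTable:
    """Build a ClonotypeTable assigning each barcode a named clonotype id."""
    rows = []
    for bc, cid in cells.items():
        rows.append((bc, cid, "TRAV11", "TRAJ18", "CA", "TRBV1", "TRBJ1-1", cid or ""))
    cols = ["barcode", "clonotype_id", "v_alpha", "j_alpha", "cdr3_alpha",
            "v_beta", "j_beta", "cdr3_beta"]
    df = pd.DataFrame(rows, columns=cols).set_index("barcode")
    keys = df[df["clonotype_id"] != ""].drop_duplicates("clonotype_id").set_index(
        "clonotype_id"
    )
    return ClonotypeTable(cells=df, keys=keys)


# -- filtering --------------------------------------------------------------


def test_filter_requires_productive_and_high_confidence():
    recs = [
        contig("C0", productive=True, hc=False),
        contig("C1", productive=False, hc=True),
        contig("C2", productive=True, hc=True),
    ]
    kept = filter_contigs(recs)
    assert [r.barcode for r in kept] == ["C2"]
    assert filter_contigs([]) == []


# -- clonotype calling ------------------------------------------------------


def test_identical_keys_share_a_clonotype_and_one_residue_separates():
    recs = paired("C0", "CASSDAGGF") + paired("C1", "CASSDAGGF") + paired(
        "C2", "CASSDAGGY"
    )
    table = call_clonotypes(recs, ["C0", "C1", "C2"])
    ids = table.cells["clonotype_id"]
    assert ids["C0"] == ids["C1"]
    assert ids["C2"] != ids["C0"]


def test_highest_umi_contig_defines_the_key():
    recs = paired("C0", "CASSAAF", umis=5)
    recs.append(contig("C0", "TRB", cdr3="CASSBBF", umis=3))
    table = call_clonotypes(recs, ["C0"])
    assert table.cells.loc["C0", "cdr3_beta"] == "CASSAAF"


def test_cells_missing_a_chain_stay_unassigned():
    recs = [contig("C0", "TRB")]  # no alpha
    table = call_clonotypes(recs, ["C0", "C1"])
    assert (table.cells["clonotype_id"] == "").all()
    assert table.assigned().empty


def test_unknown_barcodes_are_dropped_with_warning():
    recs = paired("C0", "CASSAAF") + paired("GHOST", "CASSBBF")
    with pytest.warns(UserWarning, match="unknown barcodes"):
        table = call_clonotypes(recs, ["C0"])
    assert list(table.cells.index) == ["C0"]


@settings(max_examples=40, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 4), st.integers(0, 4)),
        min_size=1,
        max_size=12,
    )
)
def test_clonotype_assignment_is_an_equivalence_relation(pairs):
    # Cells with equal (V, CDR3) keys get equal ids; unequal keys, distinct ids.
    recs, barcodes = [], []
    for i, (v_i, c_i) in enumerate(pairs):
        bc = f"C{i}"
        barcodes.append(bc)
        recs += paired(bc, f"CASS{c_i}F", v_b=f"TRBV{v_i}")
    table = call_clonotypes(recs, barcodes)
    ids = table.cells["clonotype_id"]
    for i, key_i in enumerate(pairs):
        for j, key_j in enumerate(pairs):
            assert (ids[f"C{i}"] == ids[f"C{j}"]) == (key_i == key_j)


# -- diversity --------------------------------------------------------------


def test_normalized_shannon_values():
    assert diversity_normalized_shannon([10, 10, 10, 10]) == pytest.approx(1.0)
    assert diversity_normalized_shannon([7]) == 0.0
    expected = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1)) / np.log(2)
    assert diversity_normalized_shannon([9, 1]) == pytest.approx(expected, abs=1e-4)
    assert diversity_normalized_shannon([9, 1]) == pytest.approx(0.4690, abs=1e-4)


def test_diversity_rejects_bad_input():
    with pytest.raises(ValueError):
        diversity_normalized_shannon([])
    with pytest.raises(ValueError):
        diversity_normalized_shannon([3, 0])


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(1, 50), min_size=2, max_size=10),
    st.integers(2, 5),
)
def test_diversity_invariant_to_permutation_and_scaling(counts, c):
    h = diversity_normalized_shannon(counts)
    assert 0.0 <= h <= 1.0 + 1e-12
    assert diversity_normalized_shannon(list(reversed(counts))) == pytest.approx(h)
    assert diversity_normalized_shannon([c * x for x in counts]) == pytest.approx(h)


# -- overlap ----------------------------------------------------------------


def test_overlap_counts_and_jaccard():
    table = table_from({"A0": "c1", "A1": "c2", "B0": "c2", "B1": "c3"})
    groups = ["A", "A", "B", "B"]
    shared, jaccard, comp = clonotype_overlap(table, groups)
    assert shared.loc["A", "B"] == 1
    assert jaccard.loc["A", "B"] == pytest.approx(1 / 3)
    assert jaccard.loc["A", "A"] == 1.0
    assert (jaccard.to_numpy() == jaccard.to_numpy().T).all()
    assert set(comp["clonotype_id"]) == {"c2"}
    assert comp.set_index("group")["n_cells"].to_dict() == {"A": 1, "B": 1}


def test_identical_groups_have_unit_jaccard():
    table = table_from({"A0": "c1", "A1": "c2", "B0": "c1", "B1": "c2"})
    _, jaccard, _ = clonotype_overlap(table, ["A", "A", "B", "B"])
    assert jaccard.loc["A", "B"] == 1.0


def test_private_clone_never_increases_jaccard():
    base = {"A0": "c1", "A1": "c2", "B0": "c2", "B1": "c3"}
    _, j1, _ = clonotype_overlap(table_from(base), ["A", "A", "B", "B"])
    extended = dict(base, A2="c9")  # private to A
    _, j2, _ = clonotype_overlap(table_from(extended), ["A", "A", "B", "B", "A"])
    assert j2.loc["A", "B"] <= j1.loc["A", "B"]


def test_overlap_requires_two_nonempty_groups():
    table = table_from({"A0": "c1", "B0": ""})
    with pytest.raises(ValueError):
        with pytest.warns(UserWarning):
            clonotype_overlap(table, ["A", "B"])


# -- spectratype ------------------------------------------------------------


def test_spectratype_single_length():
    table = table_from({f"C{i}": "x" for i in range(3)})
    table.cells["cdr3_beta"] = "CASSDAGGAYAEF"  # length 13
    hist, modal, freq = cdr3_spectratype(table, [f"C{i}" for i in range(3)])
    assert modal == 13
    assert hist.to_dict() == {13: 3}
    assert freq.shape == (20, 13)
    np.testing.assert_allclose(freq.sum(axis=0), 1.0)


def test_spectratype_one_hot_and_mixture_columns():
    table = table_from({"C0": "a"})
    table.cells["cdr3_beta"] = "CASSF"
    _, modal, freq = cdr3_spectratype(table, ["C0"])
    assert modal == 5
    assert (freq.to_numpy() == np.array(freq.to_numpy() >= 1.0, dtype=float)).all()
    for pos, aa in enumerate("CASSF"):
        assert freq.loc[aa, f"pos{pos + 1}"] == 1.0

    table2 = table_from({"C0": "a", "C1": "b"})
    table2.cells.loc["C0", "cdr3_beta"] = "CA"
    table2.cells.loc["C1", "cdr3_beta"] = "CG"
    _, modal2, freq2 = cdr3_spectratype(table2, ["C0", "C1"])
    assert modal2 == 2
    assert freq2.loc["C", "pos1"] == 1.0
    assert freq2.loc["A", "pos2"] == 0.5
    assert freq2.loc["G", "pos2"] == 0.5


def test_spectratype_modal_tie_goes_to_shorter():
    table = table_from({"C0": "a", "C1": "b"})
    table.cells.loc["C0", "cdr3_beta"] = "CAF"
    table.cells.loc["C1", "cdr3_beta"] = "CASSF"
    _, modal, _ = cdr3_spectratype(table, ["C0", "C1"])
    assert modal == 3
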