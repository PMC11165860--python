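"""Diversity/endemism indices: worked values, oracles, conservation laws."""

import numpy as np
import pytest

import _oracles as oracle
from conftest import random_instance
from phylohex import metrics
from phylohex.hexgrid import PresenceMatrix
from phylohex.phylo import equalize_branches, tree_from_newick


def test_worked_toy_values_exact(toy):
    m = metrics.compute_all(toy["matrix"], toy["tree"], tip_to_key=toy["tip_to_key"])
    c1, c2, c3 = toy["cells"]
    assert m.loc[[c1, c2, c3], "richness"].tolist() == [2, 2, 1]
    assert np.allclose(m.loc[[c1, c2, c3], "pd"], [3.0, 4.0, 2.0])
    assert np.allclose(m.loc[[c1, c2, c3], "pd_p"], [0.5, 4 / 6, 2 / 6])
    assert np.allclose(m.loc[[c1, c2, c3], "pe"], [2.0, 2.5, 1.5])
    assert np.allclose(m.loc[[c1, c2, c3], "we"], [1.5, 1.5, 1.0])
    assert np.allclose(m.loc[[c1, c2, c3], "cwe"], [0.75, 0.75, 1.0])
    assert m.loc[c1, "redundancy"] == pytest.approx(1 / 3)
    assert np.allclose(m.loc[[c2, c3], "redundancy"], [0.0, 0.0])
    # equal branch lengths: both ratios are exactly 1 everywhere
    assert np.allclose(m["rpd"], 1.0)
    assert np.allclose(m["rpe"], 1.0)
    assert np.allclose(m["pe_cwe"], m["pe"] / m["pd"])


def test_cell_with_all_tips_has_full_pd_and_unit_ratios(toy):
    tree = toy["tree"]
    cells = np.array([7], dtype=np.uint64)
    A = np.ones((1, 4), dtype=bool)
    matrix = PresenceMatrix(4, cells, np.arange(1, 5), A, np.array([9]))
    m = metrics.compute_all(matrix, tree, tip_to_key=toy["tip_to_key"])
    assert m["pd"].iloc[0] == pytest.approx(tree.total_length)
    assert m["pd_p"].iloc[0] == pytest.approx(1.0)
    assert m["rpd"].iloc[0] == pytest.approx(1.0)


def test_rpd_unequal_lengths_against_manual_paths():
    """Tree ((A:4,B:1)E:1,(C:1,D:1)F:1): cell {A} spans branches A and E,
    so PD = 5 of 9 total, and the unit-length comparison gives 2 of 6."""
    tree = tree_from_newick("((A:4,B:1)E:1,(C:1,D:1)F:1);")
    cmp_tree = equalize_branches(tree)
    cells = np.array([1, 2], dtype=np.uint64)
    A = np.array([[True, False, False, False], [False, True, True, True]])
    matrix = PresenceMatrix(4, cells, np.arange(1, 5), A, np.array([1, 3]))
    tk = {"A": 1, "B": 2, "C": 3, "D": 4}
    rpd = metrics.rpd_value(matrix, tree, cmp_tree, 1, tip_to_key=tk)
    assert rpd == pytest.approx((5 / 9) / (2 / 6))
    m = metrics.compute_all(matrix, tree, tip_to_key=tk)
    assert m["rpd"].iloc[0] == pytest.approx(rpd)


def test_long_restricted_branch_raises_rpe():
    tree = tree_from_newick("((A:4,B:1)E:1,(C:1,D:1)F:1);")
    cells = np.array([1, 2], dtype=np.uint64)
    A = np.array([[True, True, False, False], [False, True, True, True]])
    matrix = PresenceMatrix(4, cells, np.arange(1, 5), A, np.array([2, 3]))
    m = metrics.compute_all(matrix, tree, tip_to_key={"A": 1, "B": 2, "C": 3, "D": 4})
    # the elongated tip branch A is confined to the first cell
    assert m["rpe"].iloc[0] > 1.0


def test_rpe_invariant_under_uniform_rescaling():
    tree, matrix, tip_to_key, _ = random_instance(3)
    m1 = metrics.compute_all(matrix, tree, tip_to_key=tip_to_key)
    scaled = tree.clone()
    for e in scaled._branch_edges():
        e.length *= 7.5
    m2 = metrics.compute_all(matrix, scaled, tip_to_key=tip_to_key)
    assert np.allclose(m1["rpe"], m2["rpe"])
    assert np.allclose(m1["rpd"], m2["rpd"])
    assert np.allclose(m1["pd_p"], m2["pd_p"])


@pytest.mark.parametrize("seed", range(20))
def test_conservation_identities(seed):
    """Sum of WE over cells = species count; sum of absolute PE = tree length."""
    tree, matrix, tip_to_key, _ = random_instance(seed)
    m = metrics.compute_all(matrix, tree, tip_to_key=tip_to_key)
    assert m["we"].sum() == pytest.approx(matrix.n_species, rel=1e-9)
    assert m["pe"].sum() == pytest.approx(tree.total_length, rel=1e-9)
    assert m["pe_p"].sum() == pytest.approx(1.0, rel=1e-9)


@pytest.mark.parametrize("seed", range(25))
def test_oracle_equivalence_on_random_instances(seed):
    """PD/PE/WE/RPD/RPE match a brute-force tip-path enumeration oracle."""
    tree, matrix, tip_to_key, label_cells = random_instance(seed)
    m = metrics.compute_all(matrix, tree, tip_to_key=tip_to_key)
    for i, cell in enumerate(matrix.cells.tolist()):
        row = m.iloc[i]
        labs = label_cells[cell]
        assert row["pd"] == pytest.approx(oracle.oracle_pd(tree, labs), rel=1e-12)
        assert row["pe"] == pytest.approx(
            oracle.oracle_pe(tree, label_cells, cell), rel=1e-12
        )
        assert row["we"] == pytest.approx(oracle.oracle_we(label_cells, cell), rel=1e-12)
        assert row["rpd"] == pytest.approx(
            oracle.oracle_rpd(tree, label_cells, cell), rel=1e-12
        )
        assert row["rpe"] == pytest.approx(
            oracle.oracle_rpe(tree, label_cells, cell), rel=1e-12
        )


def test_pd_pe_monotone_when_species_added():
    tree, matrix, tip_to_key, _ = random_instance(12)
    m1 = metrics.compute_all(matrix, tree, tip_to_key=tip_to_key)
    A2 = matrix.A.copy()
    i, j = np.argwhere(~A2)[3]
    A2[i, j] = True
    rec2 = matrix.records.copy()
    rec2[i] += 1
    m2 = metrics.compute_all(
        PresenceMatrix(4, matrix.cells, matrix.species, A2, rec2),
        tree,
        tip_to_key=tip_to_key,
    )
    assert m2["pd"].iloc[i] >= m1["pd"].iloc[i]
    assert m2["pe"].iloc[i] >= m1["pe"].iloc[i]


def test_bounds_hold_on_random_instances():
    for seed in (0, 5, 9):
        tree, matrix, tip_to_key, _ = random_instance(seed)
        m = metrics.compute_all(matrix, tree, tip_to_key=tip_to_key)
        assert ((m["pd_p"] > 0) & (m["pd_p"] <= 1)).all()
        assert ((m["cwe"] > 0) & (m["cwe"] <= 1 + 1e-12)).all()
        assert (m["pe"] <= m["pd"] + 1e-12).all()
        assert ((m["redundancy"] >= 0) & (m["redundancy"] < 1)).all()


def test_single_cell_accessors_match_compute_all(toy):
    matrix, tree, tk = toy["matrix"], toy["tree"], toy["tip_to_key"]
    m = metrics.compute_all(matrix, tree, tip_to_key=tk)
    cmp_tree = equalize_branches(tree)
    for cell in toy["cells"]:
        cid = int(cell, 16)
        assert metrics.richness(matrix, cid) == m.loc[cell, "richness"]
        assert metrics.pd_value(matrix, tree, cid, tip_to_key=tk) == pytest.approx(
            m.loc[cell, "pd"]
        )
        assert metrics.pe_value(matrix, tree, cid, tip_to_key=tk) == pytest.approx(
            m.loc[cell, "pe"]
        )
        assert metrics.we_value(matrix, cid) == pytest.approx(m.loc[cell, "we"])
        assert metrics.redundancy_value(matrix, cid) == pytest.approx(
            m.loc[cell, "redundancy"]
        )
        assert metrics.rpd_value(matrix, tree, cmp_tree, cid, tip_to_key=tk) == pytest.approx(
            m.loc[cell, "rpd"]
        )
        assert metrics.rpe_value(matrix, tree, cmp_tree, cid, tip_to_key=tk) == pytest.approx(
            m.loc[cell, "rpe"]
        )


def test_permuting_cells_permutes_rows():
    tree, matrix, tip_to_key, _ = random_instance(1)
    m1 = metrics.compute_all(matrix, tree, tip_to_key=tip_to_key)
    m2 = metrics.compute_all(matrix, tree, tip_to_key=tip_to_key)
    assert m1.equals(m2)


def test_redundancy_error_on_inconsistent_cell(toy):
    with pytest.raises(KeyError):
        metrics.redundancy_value(toy["matrix"], 123456)
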