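"""Tree I/O, name matching, pruning, comparison tree, branch structures."""

import numpy as np
import pytest

from conftest import random_instance
from phylohex import fixtures
from phylohex.hexgrid import PresenceMatrix
from phylohex.phylo import (
    TreeParseError,
    branch_ranges,
    build_branch_table,
    equalize_branches,
    match_names,
    normalize_binomial,
    prune_to,
    read_tree,
    tree_from_newick,
)

TOY = "((A:1,B:1)E:1,(C:1,D:1)F:1);"


def _matrix(cells_spec, species):
    cells = np.arange(1, len(cells_spec) + 1, dtype=np.uint64)
    species = np.asarray(species, dtype=np.int64)
    A = np.zeros((len(cells_spec), len(species)), dtype=bool)
    for i, present in enumerate(cells_spec):
        for s in present:
            A[i, list(species).index(s)] = True
    return PresenceMatrix(4, cells, species, A, A.sum(axis=1))


def test_read_newick_counts_and_total_length(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text(TOY)
    t = read_tree(p)
    assert t.n_tips == 4
    assert t.n_branches == 6
    assert t.total_length == pytest.approx(6.0)


def test_read_nexus_translate_block(tmp_path):
    p = tmp_path / "t.nex"
    p.write_text(
        "#NEXUS\nBEGIN TAXA;\nDIMENSIONS NTAX=2;\nTAXLABELS Aa_bb Cc_dd;\nEND;\n"
        "BEGIN TREES;\nTRANSLATE 1 Aa_bb, 2 Cc_dd;\nTREE t = (1:1.0,2:2.0);\nEND;\n"
    )
    t = read_tree(p)
    assert sorted(t.tip_labels) == ["Aa_bb", "Cc_dd"]
    assert t.total_length == pytest.approx(3.0)


def test_malformed_tree_raises(tmp_path):
    p = tmp_path / "bad.nwk"
    p.write_text("((A:1,B:1;")
    with pytest.raises(TreeParseError):
        read_tree(p)


def test_zero_and_missing_lengths_flagged():
    with pytest.warns(UserWarning):
        t = tree_from_newick("((A:1,B),C:2);")
    assert t.n_zero_length_branches() >= 1


def test_match_names_binomial_normalization():
    t = tree_from_newick("(Acacia_dealbata:1,'Acacia mearnsii':1);")
    m = match_names(t, [(10, "Acacia dealbata"), (11, "ACACIA MEARNSII De Wild.")])
    assert m.tip_to_key == {"Acacia_dealbata": 10, "'Acacia mearnsii'": 11} or m.tip_to_key == {
        "Acacia_dealbata": 10,
        "Acacia mearnsii": 11,
    }
    assert m.unmatched_tips == [] and m.unmatched_species == []


def test_match_names_strips_infraspecific_suffix():
    assert normalize_binomial("Acacia_dealbata_subsp._dealbata") == "acacia dealbata"


def test_match_names_ott_mode():
    t = tree_from_newick("(ott123456:1,ott99:1);")
    m = match_names(t, [(5, "123456"), (6, "ott99")], label_mode="ott")
    assert m.tip_to_key == {"ott123456": 5, "ott99": 6}


def test_match_names_reports_unmatched():
    tree = fixtures.gen_tree(10, seed=0)
    species = [(k, f"Sp{k:04d}") for k in range(1, 9)]  # 8 of 10 present
    m = match_names(tree, species)
    assert len(m.tip_to_key) == 8
    assert len(m.unmatched_tips) == 2
    assert m.unmatched_species == []


def test_match_names_collision_error():
    t = tree_from_newick("(Aa_bb:1,'Aa bb':1);")
    with pytest.raises(ValueError, match="collide"):
        match_names(t, [(1, "Aa bb")])


def test_prune_identity():
    t = tree_from_newick(TOY)
    p = prune_to(t, ["A", "B", "C", "D"])
    assert p.n_tips == 4 and p.total_length == pytest.approx(6.0)


def test_prune_two_tips_sums_collapsed_lengths():
    t = tree_from_newick(TOY)
    p = prune_to(t, ["A", "C"])
    assert p.n_tips == 2
    assert p.total_length == pytest.approx(4.0)


def test_prune_single_tip_rejected():
    with pytest.raises(ValueError):
        prune_to(tree_from_newick(TOY), ["A"])


def test_prune_preserves_tip_to_root_path_lengths():
    tree = fixtures.gen_tree(20, seed=7)
    rng = np.random.default_rng(7)
    keep = list(rng.choice(tree.tip_labels, size=8, replace=False))
    before = {
        l.taxon.label: l.distance_from_root()
        for l in tree.tree.leaf_node_iter()
        if l.taxon.label in keep
    }
    pruned = prune_to(tree, keep)
    after = {l.taxon.label: l.distance_from_root() for l in pruned.tree.leaf_node_iter()}
    for lab in keep:
        assert after[lab] == pytest.approx(before[lab], rel=1e-12)


def test_equalize_branches_unit_lengths_idempotent():
    t = tree_from_newick("((A:4,B:1)E:1,(C:1,D:1)F:1);")
    e = equalize_branches(t)
    assert e.total_length == pytest.approx(6.0)
    assert all(edge.length == 1.0 for edge in e._branch_edges())
    ee = equalize_branches(e)
    assert ee.as_newick() == e.as_newick()


def test_branch_ranges_toy_counts():
    tree = tree_from_newick(TOY)
    tip_to_key = {"A": 1, "B": 2, "C": 3, "D": 4}
    matrix = _matrix([{1, 2}, {2, 3}, {4}], [1, 2, 3, 4])
    bt = branch_ranges(tree, matrix, tip_to_key)
    by_tips = {frozenset(np.flatnonzero(d) + 1): r for d, r in zip(bt.desc, bt.R)}
    assert by_tips[frozenset({1})] == 1  # A
    assert by_tips[frozenset({2})] == 2  # B
    assert by_tips[frozenset({3})] == 1  # C
    assert by_tips[frozenset({4})] == 1  # D
    assert by_tips[frozenset({1, 2})] == 2  # E
    assert by_tips[frozenset({3, 4})] == 2  # F
    assert bt.prop_lengths.sum() == pytest.approx(1.0)


def test_branch_ranges_single_cell_all_one():
    tree = tree_from_newick(TOY)
    matrix = _matrix([{1, 2, 3, 4}], [1, 2, 3, 4])
    bt = branch_ranges(tree, matrix, {"A": 1, "B": 2, "C": 3, "D": 4})
    assert (bt.R == 1).all()


def test_branch_ranges_parent_dominates_children():
    for seed in range(5):
        tree, matrix, tip_to_key, _ = random_instance(seed)
        bt = branch_ranges(tree, matrix, tip_to_key)
        sizes = bt.desc.sum(axis=1)
        for i in range(bt.n_branches):
            for j in range(bt.n_branches):
                # j strictly nested in i implies R_i >= R_j
                if sizes[j] < sizes[i] and (bt.desc[i] | bt.desc[j] == bt.desc[i]).all():
                    assert bt.R[i] >= bt.R[j]


def test_branch_ranges_monotone_under_added_occurrence():
    tree, matrix, tip_to_key, _ = random_instance(42)
    bt1 = branch_ranges(tree, matrix, tip_to_key)
    A2 = matrix.A.copy()
    empty = np.argwhere(~A2)
    i, j = empty[0]
    A2[i, j] = True
    m2 = matrix.with_incidence(A2)
    bt2 = branch_ranges(tree, m2, tip_to_key)
    assert (bt2.R >= bt1.R).all()


def test_matrix_species_missing_from_tree_rejected():
    tree = tree_from_newick(TOY)
    matrix = _matrix([{1, 9}], [1, 9])
    with pytest.raises(ValueError, match="absent|no species"):
        build_branch_table(tree, matrix.species, {"A": 1, "B": 2, "C": 3, "D": 4})
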