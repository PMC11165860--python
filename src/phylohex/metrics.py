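"""Per-cell diversity and endemism indices.

For a grid cell with species set C on a rooted tree with branch set B,
branch lengths L_b and per-branch occupied-cell ranges R_b:

    richness   = |C|
    PD         = sum of L_b over branches on the tip-to-root paths of C
    PD_P       = PD / total tree length
    RPD        = PD_P(observed tree) / PD_P(comparison tree)
    WE         = sum over species of 1 / range(s)
    CWE        = WE / richness
    PE         = sum over the same branch union of L_b / R_b
    PE_P       = PE with proportional branch lengths
    RPE        = PE_P(observed) / PE_P(comparison)
    PE_CWE     = PE / PD            (PD-corrected endemism)
    redundancy = 1 - richness / records

The comparison tree has every branch length set to one, so RPD and RPE
expose over-representation of long or short (and range-restricted)
branches.  WE and PE satisfy conservation identities: summed over all
cells, WE equals the species count and absolute PE equals the total tree
length — both are asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phylo import BranchTable, PhyloTree, branch_ranges, equalize_branches

#: metrics recomputed per null-model iteration, in this order
NULL_METRICS = ("richness", "pd_p", "rpd", "we", "cwe", "pe_p", "pe_alt_p", "rpe")


def _presence(A: np.ndarray, bt: BranchTable) -> np.ndarray:
    """Branch presence per cell: P[c, b] = cell c contains a tip of branch b."""
    return (A @ bt.desc.T) > 0


def metric_matrix(A: np.ndarray, records: np.ndarray, bt: BranchTable) -> np.ndarray:
    """All null-model metrics for an incidence array, shape (cells, metrics).

    Branch ranges are recomputed from ``A`` (they change under
    randomization); used for both observed and null communities so the two
    are always measured identically.
    """
    P = _presence(A, bt)
    R = P.sum(axis=0)
    richness = A.sum(axis=1).astype(float)

    lp = bt.prop_lengths
    pd_p = P @ lp
    B = bt.n_branches
    pd_alt_p = P.sum(axis=1) / B
    with np.errstate(divide="ignore", invalid="ignore"):
        rpd = np.where(pd_alt_p > 0, pd_p / pd_alt_p, np.nan)

        inv_R = np.where(R > 0, 1.0 / np.maximum(R, 1), 0.0)
        pe_p = P @ (lp * inv_R)
        pe_alt_p = (P @ inv_R) / B
        rpe = np.where(pe_alt_p > 0, pe_p / pe_alt_p, np.nan)

        ranges = A.sum(axis=0)
        inv_range = np.where(ranges > 0, 1.0 / np.maximum(ranges, 1), 0.0)
        we = A @ inv_range
        cwe = np.where(richness > 0, we / richness, np.nan)

    return np.column_stack([richness, pd_p, rpd, we, cwe, pe_p, pe_alt_p, rpe])


def compute_all(matrix, tree: PhyloTree, tip_to_key=None) -> pd.DataFrame:
    """Observed MetricsTable: one row per cell, indexed by the cell id string.

    The comparison (equal-branch-length) tree is built internally; both
    absolute and proportional PD/PE are emitted.
    """
    bt = branch_ranges(tree, matrix, tip_to_key)
    A = matrix.A
    P = _presence(A, bt)
    R = bt.R

    richness = A.sum(axis=1)
    total = bt.total_length
    pd_abs = P @ bt.lengths
    pd_p = pd_abs / total
    B = bt.n_branches
    pd_alt_p = P.sum(axis=1) / B
    rpd = pd_p / pd_alt_p

    inv_R = 1.0 / np.maximum(R, 1)
    pe_abs = P @ (bt.lengths * inv_R)
    pe_p = P @ (bt.prop_lengths * inv_R)
    pe_alt_p = (P @ inv_R) / B
    rpe = pe_p / pe_alt_p

    ranges = matrix.ranges()
    we = A @ (1.0 / ranges)
    cwe = we / richness
    pe_cwe = pe_abs / pd_abs
    redundancy = 1.0 - richness / matrix.records

    out = pd.DataFrame(
        {
            "richness": richness.astype(int),
            "records": matrix.records,
            "pd": pd_abs,
            "pd_p": pd_p,
            "rpd": rpd,
            "we": we,
            "cwe": cwe,
            "pe": pe_abs,
            "pe_p": pe_p,
            "pe_alt_p": pe_alt_p,
            "rpe": rpe,
            "pe_cwe": pe_cwe,
            "redundancy": redundancy,
        },
        index=pd.Index(matrix.cell_strs(), name="cell"),
    )
    assert np.isfinite(out.drop(columns=["rpd", "rpe"]).to_numpy()).all()
    return out


# ---------------------------------------------------------------------------
# single-cell accessors (convenience / didactic forms of the same formulas)
# ---------------------------------------------------------------------------


def richness(matrix, cell) -> int:
    return int(matrix.A[matrix.cell_index(cell)].sum())


def pd_value(matrix, tree: PhyloTree, cell, proportional: bool = False, tip_to_key=None):
    """Faith's PD of one cell: length of the union of tip-to-root paths."""
    bt = branch_ranges(tree, matrix, tip_to_key)
    row = _presence(matrix.A[[matrix.cell_index(cell)]], bt)[0]
    val = float(bt.lengths[row].sum())
    return val / bt.total_length if proportional else val


def rpd_value(matrix, tree: PhyloTree, comparison_tree: PhyloTree, cell, tip_to_key=None):
    if comparison_tree.n_branches != tree.n_branches:
        raise ValueError("comparison tree topology does not match")
    a = pd_value(matrix, tree, cell, proportional=True, tip_to_key=tip_to_key)
    b = pd_value(matrix, comparison_tree, cell, proportional=True, tip_to_key=tip_to_key)
    return a / b if b > 0 else float("nan")


def we_value(matrix, cell) -> float:
    i = matrix.cell_index(cell)
    return float((1.0 / matrix.ranges()[matrix.A[i]]).sum())


def cwe_value(matrix, cell) -> float:
    return we_value(matrix, cell) / richness(matrix, cell)


def pe_value(matrix, tree: PhyloTree, cell, proportional: bool = False, tip_to_key=None):
    """Phylogenetic endemism: PD with branches down-weighted by their range."""
    bt = branch_ranges(tree, matrix, tip_to_key)
    row = _presence(matrix.A[[matrix.cell_index(cell)]], bt)[0]
    lengths = bt.prop_lengths if proportional else bt.lengths
    return float((lengths[row] / bt.R[row]).sum())


def rpe_value(matrix, tree: PhyloTree, comparison_tree: PhyloTree, cell, tip_to_key=None):
    if comparison_tree.n_branches != tree.n_branches:
        raise ValueError("comparison tree topology does not match")
    a = pe_value(matrix, tree, cell, proportional=True, tip_to_key=tip_to_key)
    b = pe_value(matrix, comparison_tree, cell, proportional=True, tip_to_key=tip_to_key)
    return a / b if b > 0 else float("nan")


def redundancy_value(matrix, cell) -> float:
    """Sampling-completeness proxy: 1 - richness / records."""
    i = matrix.cell_index(cell)
    rich = matrix.A[i].sum()
    rec = matrix.records[i]
    if rec < rich or rich < 1:
        raise ValueError(f"cell {cell}: records ({rec}) < richness ({rich})")
    return float(1.0 - rich / rec)


def make_comparison_tree(tree: PhyloTree) -> PhyloTree:
    return equalize_branches(tree)
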