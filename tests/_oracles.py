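"""Independent brute-force oracles for the diversity indices.

These deliberately avoid the package's vectorized mask/matmul machinery:
PD is computed by explicitly walking tip-to-root paths and unioning edges,
PE by enumerating every branch's descendant tips and occupied cells.
"""

from __future__ import annotations


def _edges_on_paths(tree, labels):
    """Set of edges on the tip-to-root paths of the labelled tips."""
    edges = set()
    for leaf in tree.tree.leaf_node_iter():
        if leaf.taxon.label not in labels:
            continue
        node = leaf
        while node is not None:
            edge = node.edge
            if node.parent_node is not None or edge.length is not None:
                edges.add(edge)
            node = node.parent_node
    return edges


def _branch_list(tree):
    out = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is not None or node.edge.length is not None:
            out.append(node.edge)
    return out


def _desc_labels(edge):
    head = edge.head_node
    return {leaf.taxon.label for leaf in head.leaf_iter()}


def oracle_pd(tree, labels, proportional=False):
    total = sum(e.length for e in _branch_list(tree))
    val = sum(e.length for e in _edges_on_paths(tree, labels))
    return val / total if proportional else val


def oracle_branch_ranges(tree, cells):
    """edge -> number of cells whose species set intersects its tips."""
    out = {}
    for edge in _branch_list(tree):
        desc = _desc_labels(edge)
        out[edge] = sum(1 for labs in cells.values() if desc & set(labs))
    return out


def oracle_pe(tree, cells, cell, proportional=False):
    R = oracle_branch_ranges(tree, cells)
    total = sum(e.length for e in _branch_list(tree))
    val = 0.0
    for edge in _edges_on_paths(tree, cells[cell]):
        length = edge.length / total if proportional else edge.length
        val += length / R[edge]
    return val


def oracle_we(cells, cell):
    ranges = {}
    for labs in cells.values():
        for s in labs:
            ranges[s] = ranges.get(s, 0) + 1
    return sum(1.0 / ranges[s] for s in cells[cell])


def oracle_rpd(tree, cells, cell):
    """RPD via an explicit unit-branch-length comparison computation."""
    obs = oracle_pd(tree, cells[cell], proportional=True)
    branches = _branch_list(tree)
    present = _edges_on_paths(tree, cells[cell])
    cmp_pd = len(present) / len(branches)
    return obs / cmp_pd


def oracle_rpe(tree, cells, cell):
    obs = oracle_pe(tree, cells, cell, proportional=True)
    R = oracle_branch_ranges(tree, cells)
    branches = _branch_list(tree)
    present = _edges_on_paths(tree, cells[cell])
    cmp_pe = sum((1.0 / len(branches)) / R[e] for e in present)
    return obs / cmp_pe
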