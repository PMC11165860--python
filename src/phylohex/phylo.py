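"""Phylogenetic trees: parsing, name matching, pruning, branch structures.

Trees are used as rooted, as supplied (no re-rooting).  The "branch set" of
a tree is every edge with a parent plus the root edge when the source file
gives it a length; the root edge then counts toward the total length and
contributes to the diversity of every non-empty cell alike.

Tip labels are reconciled with occurrence species either as Latin binomials
(case-insensitive, underscores/quotes normalized, infraspecific and
authorship suffixes beyond the first two words dropped) or as numeric
OpenTree ids ("ott" prefix stripped).
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from pathlib import Path

import dendropy
import numpy as np


class TreeParseError(ValueError):
    pass


class PhyloTree:
    """A rooted, branch-length-bearing tree (thin wrapper over dendropy)."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.tree.is_rooted = True
        self._defaulted = 0
        for edge in self._branch_edges():
            if edge.length is None:
                edge.length = 0.0
                self._defaulted += 1
        if self._defaulted:
            warnings.warn(
                f"{self._defaulted} branch(es) had no length; defaulted to 0"
            )

    # -- structure ----------------------------------------------------------

    def _branch_edges(self):
        """Edges in the branch set, in a stable preorder."""
        edges = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                edges.append(node.edge)
            elif node.edge.length is not None:
                edges.append(node.edge)  # explicit root edge
        return edges

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def n_branches(self) -> int:
        return len(self._branch_edges())

    @property
    def total_length(self) -> float:
        return float(sum(e.length for e in self._branch_edges()))

    def n_zero_length_branches(self) -> int:
        return sum(1 for e in self._branch_edges() if e.length == 0)

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1))

    def write(self, path) -> Path:
        path = Path(path)
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True)
        return path

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self):
        return f"PhyloTree({self.n_tips} tips, total_length={self.total_length:g})"


def read_tree(path, format: str | None = None) -> PhyloTree:
    """Read a rooted tree from Newick or Nexus (format inferred by default)."""
    path = Path(path)
    if format is None:
        text = path.read_text()
        format = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema=format, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeParseError(f"cannot parse {path.name} as {format}: {exc}") from exc
    if tree.seed_node is None or not any(tree.leaf_node_iter()):
        raise TreeParseError(f"{path.name}: tree has no tips")
    return PhyloTree(tree)


def tree_from_newick(newick: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise TreeParseError(f"cannot parse newick string: {exc}") from exc
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# name matching
# ---------------------------------------------------------------------------


def normalize_binomial(label: str) -> str:
    """First two words of a label, case-folded; quotes/underscores stripped."""
    s = label.strip().strip("'\"").replace("_", " ")
    words = s.split()
    return " ".join(words[:2]).casefold()


_OTT_RE = re.compile(r"(?:ott)?_?(\d+)$", re.IGNORECASE)


def _ott_id(label: str) -> int | None:
    m = _OTT_RE.fullmatch(label.strip().strip("'\""))
    return int(m.group(1)) if m else None


@dataclasses.dataclass
class NameMatch:
    tip_to_key: dict  # tip label -> species_key
    unmatched_tips: list
    unmatched_species: list


def match_names(tree: PhyloTree, species, label_mode: str = "binomial") -> NameMatch:
    """Reconcile tree tip labels with occurrence species.

    ``species`` is an iterable of ``(species_key, species_name_or_ott)``.
    In binomial mode names match case-insensitively after normalization; in
    ott mode tip labels like ``ott123456`` match numeric OpenTree ids.
    Raises on tip labels that collide after normalization.
    """
    if label_mode not in ("binomial", "ott"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    labels = tree.tip_labels

    if label_mode == "binomial":
        norm = {}
        collisions = []
        for lab in labels:
            key = normalize_binomial(lab)
            if key in norm:
                collisions.append((norm[key], lab))
            norm.setdefault(key, lab)
        if collisions:
            raise ValueError(f"tip labels collide after normalization: {collisions}")
        lookup = {}
        for sp_key, sp_name in species:
            if sp_name is None:
                continue
            nkey = normalize_binomial(str(sp_name))
            if nkey in lookup and lookup[nkey] != sp_key:
                warnings.warn(f"species name {sp_name!r} maps to multiple keys; keeping first")
                continue
            lookup.setdefault(nkey, sp_key)
        tip_to_key = {
            lab: lookup[normalize_binomial(lab)]
            for lab in labels
            if normalize_binomial(lab) in lookup
        }
        matched_keys = set(tip_to_key.values())
        unmatched_species = [
            (k, n) for k, n in species if k not in matched_keys
        ]
    else:
        tip_ids = {}
        collisions = []
        for lab in labels:
            oid = _ott_id(lab)
            if oid is None:
                continue
            if oid in tip_ids:
                collisions.append((tip_ids[oid], lab))
            tip_ids.setdefault(oid, lab)
        if collisions:
            raise ValueError(f"tip labels collide after normalization: {collisions}")
        lookup = {}
        for sp_key, ott in species:
            oid = _ott_id(str(ott)) if ott is not None else None
            if oid is not None:
                lookup.setdefault(oid, sp_key)
        tip_to_key = {lab: lookup[oid] for oid, lab in tip_ids.items() if oid in lookup}
        matched_keys = set(tip_to_key.values())
        unmatched_species = [(k, n) for k, n in species if k not in matched_keys]

    unmatched_tips = [lab for lab in labels if lab not in tip_to_key]
    return NameMatch(tip_to_key, unmatched_tips, unmatched_species)


# ---------------------------------------------------------------------------
# pruning and the equal-branch-length comparison tree
# ---------------------------------------------------------------------------


def prune_to(tree: PhyloTree, keep_labels) -> PhyloTree:
    """Smallest subtree containing the kept tips and the original root.

    Internal unbranched nodes are collapsed with their lengths summed, so
    tip-to-root path lengths are preserved; the root node itself is retained
    even if it is left with a single child.
    """
    keep = set(keep_labels)
    if len(keep) < 2:
        raise ValueError("pruning requires at least 2 matched tips")
    t = tree.tree.clone(depth=1)
    present = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    missing = keep - present
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)[:5]}")

    changed = True
    while changed:
        changed = False
        for leaf in list(t.leaf_node_iter()):
            if leaf.taxon is None or leaf.taxon.label not in keep:
                parent = leaf.parent_node
                if parent is None:
                    raise ValueError("pruning removed the whole tree")
                parent.remove_child(leaf)
                changed = True
    # collapse internal unifurcations (keep the seed node)
    for node in list(t.preorder_node_iter()):
        if node is t.seed_node or node.is_leaf():
            continue
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
    t.purge_taxon_namespace()
    return PhyloTree(t)


def equalize_branches(tree: PhyloTree) -> PhyloTree:
    """Comparison tree: same topology, every branch length set to 1.

    Ratios downstream use proportional lengths, so the constant is
    immaterial; 1 makes the total length equal the branch count.
    """
    out = tree.clone()
    for edge in out._branch_edges():
        edge.length = 1.0
    return out


# ---------------------------------------------------------------------------
# per-branch descendant sets and occupied-cell ranges
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BranchTable:
    """Per-branch structure aligned to a species ordering.

    desc[b, s] is True when species s descends from branch b; R[b] is the
    number of grid cells whose species set intersects desc[b] (the branch's
    occupied-cell range).  prop_lengths sum to 1.
    """

    lengths: np.ndarray  # (B,)
    desc: np.ndarray  # (B, S) bool
    species: np.ndarray  # (S,) keys, the alignment order
    R: np.ndarray | None = None  # (B,) occupied-cell counts

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    @property
    def prop_lengths(self) -> np.ndarray:
        return self.lengths / self.lengths.sum()

    @property
    def n_branches(self) -> int:
        return len(self.lengths)


def build_branch_table(tree: PhyloTree, species_order, tip_to_key=None) -> BranchTable:
    """Branch lengths and descendant-species masks for a pruned tree.

    ``species_order`` fixes the column order (PresenceMatrix.species);
    ``tip_to_key`` maps tip labels to species keys (labels parsed as integer
    keys when omitted).  Every species in the order must be a tip.
    """
    species_order = np.asarray(species_order, dtype=np.int64)
    S = len(species_order)
    col = {int(k): i for i, k in enumerate(species_order)}

    def _key_of(label):
        if tip_to_key is not None:
            return tip_to_key.get(label)
        try:
            return int(label)
        except (TypeError, ValueError):
            return None

    masks = {}
    lengths = []
    rows = []
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            m = np.zeros(S, dtype=bool)
            key = _key_of(node.taxon.label if node.taxon else None)
            if key is None or key not in col:
                raise ValueError(
                    f"tip {node.taxon.label if node.taxon else '?'} has no species in the matrix; "
                    "prune the tree to the matched species first"
                )
            m[col[key]] = True
        else:
            m = np.zeros(S, dtype=bool)
            for ch in node.child_nodes():
                m |= masks[ch]
        masks[node] = m
        if node.parent_node is not None or node.edge.length is not None:
            lengths.append(float(node.edge.length or 0.0))
            rows.append(m)

    covered = np.zeros(S, dtype=bool)
    for m in rows:
        covered |= m
    if not covered.all():
        missing = species_order[~covered].tolist()
        raise ValueError(f"species absent from tree: {missing[:5]}")

    return BranchTable(
        lengths=np.asarray(lengths, dtype=float),
        desc=np.asarray(rows, dtype=bool),
        species=species_order,
    )


def branch_ranges(tree: PhyloTree, matrix, tip_to_key=None) -> BranchTable:
    """Branch table with occupied-cell ranges computed from a presence matrix."""
    bt = build_branch_table(tree, matrix.species, tip_to_key)
    P = matrix.A @ bt.desc.T  # (cells, branches) intersection counts
    bt.R = (P > 0).sum(axis=0).astype(np.int64)
    return bt
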