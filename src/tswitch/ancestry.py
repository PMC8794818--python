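"""Rooted-tree handling, ancestral annotation, and tree-level bookkeeping.

Trees are rooted newick trees with unique, labeled internal nodes
(PAGAN2-style ancestor-annotated output: every node label maps to one
record of the accompanying alignment FASTA).  When only leaves carry
sequences, ``fitch_reconstruct`` provides a parsimony stand-in for the
ancestral states so that end-to-end runs remain possible without an
external maximum-likelihood reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy
import numpy as np

from .seqcore import GAP, IUPAC_SETS

#: Fitch state order used for deterministic tie-breaking (gap sorts last).
_STATE_ORDER = {s: i for i, s in enumerate("ACGT" + GAP)}


def node_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


def load_tree(source: str, from_path: bool = True) -> dendropy.Tree:
    """Load a rooted newick tree with internal node labels preserved."""
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if from_path:
        tree = dendropy.Tree.get(path=str(source), **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def iter_parent_child(
    tree: dendropy.Tree,
) -> Iterator[tuple[dendropy.Node, dendropy.Node]]:
    """Yield every (parent, child) edge whose parent is a nonroot node.

    The root is never used as a reference for branch comparisons; edges are
    yielded in deterministic preorder.
    """
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is root or node.is_leaf():
            continue
        for child in node.child_nodes():
            yield node, child


@dataclass
class AnnotatedNode:
    """A tree node with its aligned sequence and structural annotation."""

    label: str
    gapped_seq: str
    structure: str = ""  # dot-bracket on the ungapped sequence
    mask: Optional[np.ndarray] = None  # per-alignment-column quality mask
    level: int = -1
    is_leaf: bool = False
    gapped_structure: str = field(default="", repr=False)

    @property
    def seq(self) -> str:
        return self.gapped_seq.replace(GAP, "")

    def __post_init__(self):
        if self.structure and not self.gapped_structure:
            from .structure import gapped_structure

            self.gapped_structure = gapped_structure(self.structure, self.gapped_seq)


def _leaf_state_set(char: str) -> frozenset[str]:
    if char == GAP:
        return frozenset({GAP})
    try:
        return IUPAC_SETS[char]
    except KeyError as exc:
        raise ValueError(f"invalid character {char!r} in leaf sequence") from exc


def fitch_reconstruct(
    tree: dendropy.Tree, leaf_alignment: dict[str, str]
) -> dict[str, str]:
    """Column-wise Fitch parsimony ancestral reconstruction.

    The gap symbol is treated as a fifth character state.  Bottom-up:
    intersection of child state sets if nonempty, else union.  Top-down:
    each internal node takes its parent's state when admissible, the root
    breaking ties by the fixed state order A < C < G < T < gap.  Leaf
    ambiguity codes contribute their base sets.
    """
    leaves = [n for n in tree.leaf_node_iter()]
    for leaf in leaves:
        if node_label(leaf) not in leaf_alignment:
            raise ValueError(f"leaf {node_label(leaf)!r} has no sequence")
    lengths = {len(s) for s in leaf_alignment.values()}
    if len(lengths) > 1:
        raise ValueError("leaf sequences must be aligned to equal length")
    ncol = lengths.pop() if lengths else 0

    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    result: dict[str, list[str]] = {node_label(n): [] for n in internals}

    for col in range(ncol):
        sets: dict[int, frozenset] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                sets[id(node)] = _leaf_state_set(leaf_alignment[node_label(node)][col])
            else:
                acc: Optional[frozenset] = None
                for child in node.child_nodes():
                    s = sets[id(child)]
                    acc = s if acc is None else (acc & s or acc | s)
                sets[id(node)] = acc
        # top-down resolution
        chosen: dict[int, str] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            s = sets[id(node)]
            parent = node.parent_node
            if parent is not None and chosen[id(parent)] in s:
                state = chosen[id(parent)]
            else:
                state = min(s, key=_STATE_ORDER.__getitem__)
            chosen[id(node)] = state
            result[node_label(node)].append(state)
    return {label: "".join(chars) for label, chars in result.items()}


def branch_level(tree: dendropy.Tree) -> dict[str, int]:
    """Assign each node the lowest possible tree level.

    Terminal nodes are level 0; an internal node is one above the minimum of
    its child levels.  The root receives a level too but is flagged by the
    caller (its branch does not exist and is excluded from normalisation).
    """
    levels: dict[str, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            levels[node_label(node)] = 0
        else:
            levels[node_label(node)] = 1 + min(
                levels[node_label(c)] for c in node.child_nodes()
            )
    return levels


def normalized_level_counts(
    records: list[tuple[str, str]],
    trees: dict[str, dendropy.Tree],
) -> dict[int, float]:
    """Per-level event rates normalised by branch counts of affected trees.

    ``records`` are (tree_id, node_label) pairs locating each qualifying
    event at the child node of its branch.  Counts at each level are divided
    by the total number of branches of that level across the trees that
    carry at least one record; the root (which has no branch) is excluded
    from the denominators.
    """
    if not records:
        return {}
    affected = {tree_id for tree_id, _ in records}
    level_of: dict[str, dict[str, int]] = {}
    denom: dict[int, int] = {}
    for tree_id in sorted(affected):
        tree = trees[tree_id]
        levels = branch_level(tree)
        level_of[tree_id] = levels
        root = node_label(tree.seed_node)
        for label, lev in levels.items():
            if label == root:
                continue
            denom[lev] = denom.get(lev, 0) + 1
    counts: dict[int, int] = {}
    for tree_id, label in records:
        lev = level_of[tree_id][label]
        counts[lev] = counts.get(lev, 0) + 1
    return {lev: counts.get(lev, 0) / denom[lev] for lev in sorted(denom)}
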