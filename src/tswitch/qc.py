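"""Quality control: high-quality region masks and simulation correction.

A 10-column sliding window over the alignment passes for an internal node
when (1) at least 9 base identities against at least one child, (2) at
least 6 structure identities against that same child, and (3) at least 9
base identities against the node's own parent.  A column is high quality
iff it lies inside at least one passing window.  Homologous IUPAC
uncertainties are unified before comparison.
"""

from __future__ import annotations

import numpy as np

from .ancestry import AnnotatedNode
from .seqcore import GAP, unify_uncertainties
from .structure import structure_identity


def _base_identity(a: str, b: str) -> np.ndarray:
    """Column-wise base identity after unifying overlapping IUPAC ranges.

    Shared gap columns count as identities (no evidence of change); a gap
    opposite a base does not.
    """
    ua, ub = unify_uncertainties(a, b)
    return np.fromiter(
        (x == y for x, y in zip(ua, ub)), dtype=np.bool_, count=len(ua)
    )


def high_quality_mask(
    node: AnnotatedNode,
    parent: AnnotatedNode,
    children: list[AnnotatedNode],
    window: int = 10,
    min_base_child: int = 9,
    min_struct_child: int = 6,
    min_base_parent: int = 9,
) -> np.ndarray:
    """Per-alignment-column high-quality mask for one internal node.

    The base and structure thresholds must be met jointly by a single child
    within the window.  Windows shorter than ``window`` at sequence ends are
    skipped.
    """
    if parent is None or not children:
        raise ValueError("high_quality_mask needs a parent and at least one child")
    ncol = len(node.gapped_seq)
    mask = np.zeros(ncol, dtype=bool)
    if ncol < window:
        return mask

    base_parent = _base_identity(node.gapped_seq, parent.gapped_seq)
    child_stats = []
    for child in children:
        base_c = _base_identity(node.gapped_seq, child.gapped_seq)
        struct_c = structure_identity(
            node.structure, node.gapped_seq, child.structure, child.gapped_seq
        )
        child_stats.append((base_c, struct_c))

    def _win_sums(arr: np.ndarray) -> np.ndarray:
        cs = np.concatenate(([0], np.cumsum(arr)))
        return cs[window:] - cs[:-window]

    parent_ok = _win_sums(base_parent) >= min_base_parent
    child_ok = np.zeros(ncol - window + 1, dtype=bool)
    for base_c, struct_c in child_stats:
        child_ok |= (_win_sums(base_c) >= min_base_child) & (
            _win_sums(struct_c) >= min_struct_child
        )
    passing = parent_ok & child_ok
    for s in np.nonzero(passing)[0]:
        mask[s : s + window] = True
    return mask


def interval_in_mask(mask: np.ndarray, columns: range) -> bool:
    """True iff every column of the (alignment-column) interval is high quality."""
    if len(columns) == 0:
        return True
    return bool(mask[columns.start : columns.stop].all())


def mask_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """High-quality runs as 0-based half-open alignment-column intervals."""
    out: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(mask):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def inheritance_check(
    child: AnnotatedNode,
    columns: range,
    grandchildren: list[AnnotatedNode],
) -> bool:
    """Identical-form inheritance by at least one of the node's own children.

    Applies only when the query node is internal; terminal queries pass
    vacuously.
    """
    if child.is_leaf or not grandchildren:
        return True
    segment = child.gapped_seq[columns.start : columns.stop]
    return any(
        g.gapped_seq[columns.start : columns.stop] == segment for g in grandchildren
    )


def effective_length(
    masks: dict[str, np.ndarray], gapped_seqs: dict[str, str]
) -> int:
    """Total internal-node bases inside high-quality columns."""
    total = 0
    for label, mask in masks.items():
        seq = gapped_seqs[label]
        total += sum(
            1 for i, c in enumerate(seq) if c != GAP and i < len(mask) and mask[i]
        )
    return total


def correction_factor(empirical_len: int, simulated_len: int) -> float:
    """Empirical effective length divided by simulated effective length."""
    if simulated_len <= 0:
        raise ValueError("simulated effective length must be positive")
    return empirical_len / simulated_len
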