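"""Hairpin-loop extraction and loop motif/length frequency comparisons.

Loops are harvested from nonroot internal (ancestral) nodes that have at
least one terminal child; the background frequencies come from all
qualifying loops, and the foreground set from hairpins carrying at least
one instantaneous compensatory mutation.  Motif patterns are IUPAC strings
on the DNA alphabet (GNRA, TNCG, CTTG, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .seqcore import IUPAC_SETS, WC_PAIRS, reverse_complement
from .structure import HairpinElement, has_ambiguity

#: tetraloop families known to form exceptionally stable hairpins
STABLE_MOTIFS = ("GNRA", "TNCG", "CTTG")


@dataclass(frozen=True)
class LoopRecord:
    """One extracted hairpin loop (unambiguous, Watson-Crick-closed)."""

    sequence: str
    node: str
    closing_pair: str
    has_instantaneous_cm: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


def loop_record_from_hairpin(
    h: HairpinElement,
    seq: str,
    node: str,
    has_cm: bool = False,
) -> Optional[LoopRecord]:
    """Build a LoopRecord if the hairpin passes the loop-quality filters.

    The closing pair must be Watson-Crick and the loop sequence free of
    ambiguity codes; otherwise ``None``.
    """
    i, j = h.closing_pair
    closing = seq[i] + seq[j]
    if closing not in WC_PAIRS:
        return None
    lo, hi = h.loop
    if has_ambiguity(seq, lo, hi):
        return None
    return LoopRecord(
        sequence=seq[lo:hi],
        node=node,
        closing_pair=closing,
        has_instantaneous_cm=has_cm,
    )


def extract_loops(
    tree,
    annotations: dict,
    hairpins: dict,
    masks: Optional[dict] = None,
    cm_loops: frozenset = frozenset(),
) -> list[LoopRecord]:
    """Harvest qualifying loops from nonroot internal nodes with a terminal child.

    ``hairpins`` maps node label -> extracted HairpinElements; ``masks``
    (optional) maps node label -> high-quality column mask, and a loop is
    kept only if its hairpin lies entirely inside high-quality columns.
    ``cm_loops`` is a set of (node_label, loop_interval) pairs marking
    hairpins that carry at least one instantaneous CM.
    """
    from .ancestry import node_label as _label
    from .qc import interval_in_mask
    from .seqcore import interval_columns

    records: list[LoopRecord] = []
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is root or node.is_leaf():
            continue
        if not any(c.is_leaf() for c in node.child_nodes()):
            continue
        label = _label(node)
        ann = annotations[label]
        for h in hairpins.get(label, []):
            if masks is not None:
                mask = masks.get(label)
                if mask is None:
                    continue
                cols = interval_columns(ann.gapped_seq, h.span[0], h.span[1])
                if not interval_in_mask(mask, cols):
                    continue
            rec = loop_record_from_hairpin(
                h,
                ann.seq,
                label,
                has_cm=(label, h.loop) in cm_loops,
            )
            if rec is not None:
                records.append(rec)
    return records


def match_motif(loop: str, pattern: str) -> bool:
    """True iff the loop matches the IUPAC pattern position by position."""
    if len(loop) != len(pattern):
        return False
    return all(
        base in IUPAC_SETS.get(code, frozenset()) for base, code in zip(loop, pattern)
    )


def loop_frequency_table(
    cm_loops: Sequence[LoopRecord],
    all_loops: Sequence[LoopRecord],
    motifs: Sequence[str] = STABLE_MOTIFS,
    lengths: Iterable[int] = range(3, 9),
) -> pd.DataFrame:
    """Motif and loop-length frequencies: CM-hairpin set versus background.

    For each motif and each loop length, reports the frequency among
    hairpins with instantaneous CMs, the background frequency, and a
    two-sided one-proportion z-test p-value with the background frequency
    as the null proportion.  Rows with degenerate background frequencies
    (0 or 1) carry NaN statistics.
    """
    from .stats import one_proportion_ztest

    if not all_loops:
        raise ValueError("empty background loop set")
    if not cm_loops:
        raise ValueError("empty CM loop set")
    n_cm, n_bg = len(cm_loops), len(all_loops)
    rows = []
    items = [("motif", m) for m in motifs] + [("length", l) for l in lengths]
    for kind, key in items:
        if kind == "motif":
            in_cm = sum(1 for r in cm_loops if match_motif(r.sequence, key))
            in_bg = sum(1 for r in all_loops if match_motif(r.sequence, key))
        else:
            in_cm = sum(1 for r in cm_loops if r.length == key)
            in_bg = sum(1 for r in all_loops if r.length == key)
        p0 = in_bg / n_bg
        if 0.0 < p0 < 1.0:
            z, p = one_proportion_ztest(in_cm, n_cm, p0)
        else:
            z, p = math.nan, math.nan
        rows.append(
            {
                "kind": kind,
                "key": str(key),
                "cm_freq": in_cm / n_cm,
                "background_freq": p0,
                "z": z,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def forward_reverse_ratio(loops: Sequence[LoopRecord], sequence: str) -> float:
    """Count ratio of a loop sequence to its reverse complement.

    Returns ``math.inf`` when the reverse complement is absent from the
    background multiset (and the forward sequence is present).
    """
    fwd = sum(1 for r in loops if r.sequence == sequence)
    rc = reverse_complement(sequence)
    rev = sum(1 for r in loops if r.sequence == rc)
    if rev == 0:
        return math.inf if fwd > 0 else math.nan
    return fwd / rev
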