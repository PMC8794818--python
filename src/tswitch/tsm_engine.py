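"""The four-switch-point template-switch mutation (TSM) model.

A TSM replaces the *target* interval [p1, p4) of the parent sequence with
the reverse complement of the *source* interval [p3, p2), mimicking DNA
replication briefly copying a nearby template in reverse-complement
orientation before returning to the original strand.  All four switch
points are 0-based coordinates on the parent's ungapped sequence.

``find_tsm`` inverts the model: given a parent (reference) and child
(query) sequence of one tree branch, it enumerates all admissible events —
child target segment exactly equal to the reverse complement of a parent
source segment, with configurable minimum copied length, maximum
source/target distance, and minimum number of explained differences — and
ranks them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib

from .seqcore import GAP, reverse_complement

LEFTWARD = "leftward"
RIGHTWARD = "rightward"


@dataclass(frozen=True)
class TSMEvent:
    """A template-switch event on one parent->child branch.

    ``p1..p4`` are parent ungapped coordinates; the target interval
    [p1, p4) is replaced by the reverse complement of the source interval
    [p3, p2).  ``child_target`` is the replacing segment's interval on the
    child's ungapped coordinates and ``explained`` the number of aligned
    parent/child differences inside the target removed by the event.
    """

    p1: int
    p2: int
    p3: int
    p4: int
    copied_len: int
    explained: int
    child_target: tuple[int, int] = (0, 0)

    @property
    def source(self) -> tuple[int, int]:
        return (self.p3, self.p2)

    @property
    def target(self) -> tuple[int, int]:
        return (self.p1, self.p4)

    @property
    def jump(self) -> str:
        return classify_jump(self)

    def sort_key(self):
        # ranking: explained desc, copied_len desc (prefer the maximal
        # extension of a copy), leftmost target, leftmost source
        return (-self.explained, -self.copied_len, self.p1, self.p3)


def apply_tsm(seq: str, p1: int, p2: int, p3: int, p4: int) -> str:
    """Apply a TSM generatively: seq[:p1] + revcomp(seq[p3:p2]) + seq[p4:]."""
    n = len(seq)
    if not (0 <= p3 < p2 <= n or p3 == p2):
        if not (0 <= p3 <= p2 <= n):
            raise ValueError(f"source [{p3},{p2}) out of range for length {n}")
    if not (0 <= p3 <= p2 <= n):
        raise ValueError(f"source [{p3},{p2}) out of range for length {n}")
    if not (0 <= p1 <= p4 <= n):
        raise ValueError(f"target [{p1},{p4}) out of range for length {n}")
    return seq[:p1] + reverse_complement(seq[p3:p2]) + seq[p4:]


def classify_jump(event: TSMEvent) -> str:
    """Strand interpretation of the switch jump.

    ``rightward`` (p2 > p1) is only producible by an interstrand-forward
    switch; ``leftward`` covers the sequence-indistinguishable intrastrand
    and interstrand-backward switches.  The degenerate p1 == p2 boundary is
    assigned to leftward and excluded from strand-ratio summaries.
    """
    return RIGHTWARD if event.p2 > event.p1 else LEFTWARD


def pairwise_align(ref: str, query: str) -> tuple[str, str]:
    """Global pairwise alignment plumbing (unit costs), as aligned strings."""
    if not ref or not query:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(query, ref, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, ref)
    return nice["target_aligned"], nice["query_aligned"]


class _AlignedPair:
    """Coordinate bookkeeping between a parent/child aligned sequence pair."""

    def __init__(self, ref_aln: str, query_aln: str):
        if len(ref_aln) != len(query_aln):
            raise ValueError("aligned strings must have equal length")
        self.ref_aln = ref_aln
        self.query_aln = query_aln
        self.ncol = len(ref_aln)
        self.ref = ref_aln.replace(GAP, "")
        self.query = query_aln.replace(GAP, "")
        # column of each parent/child residue
        self.ref_col = [i for i, c in enumerate(ref_aln) if c != GAP]
        self.query_col = [i for i, c in enumerate(query_aln) if c != GAP]
        # prefix counts per column boundary
        self.q_before = [0] * (self.ncol + 1)
        self.diff_before = [0] * (self.ncol + 1)
        for i in range(self.ncol):
            self.q_before[i + 1] = self.q_before[i] + (query_aln[i] != GAP)
            self.diff_before[i + 1] = self.diff_before[i] + (
                ref_aln[i] != query_aln[i]
            )
        # insertion runs (gap-in-parent columns) attach to the parent
        # residue that follows them, so a pure-insertion target [p, p)
        # spans exactly its run of inserted child bases
        self.run_start = [0] * (len(self.ref) + 1)
        for p in range(len(self.ref) + 1):
            c = self.col_bound(p)
            while c > 0 and ref_aln[c - 1] == GAP:
                c -= 1
            self.run_start[p] = c

    def col_bound(self, p: int) -> int:
        """Alignment column of the parent boundary index p (0..len(ref))."""
        return self.ref_col[p] if p < len(self.ref_col) else self.ncol

    def target_columns(self, p1: int, p4: int) -> tuple[int, int]:
        return self.run_start[p1], self.col_bound(p4)

    def child_segment(self, p1: int, p4: int) -> tuple[int, int]:
        """Child ungapped interval aligned to parent target [p1, p4)."""
        c_lo, c_hi = self.target_columns(p1, p4)
        return self.q_before[c_lo], self.q_before[c_hi]

    def diffs_in(self, p1: int, p4: int) -> int:
        c_lo, c_hi = self.target_columns(p1, p4)
        return self.diff_before[c_hi] - self.diff_before[c_lo]

    def diff_parent_positions(self) -> list[int]:
        """Parent boundary indices adjacent to each differing column."""
        out = []
        p = 0
        for i in range(self.ncol):
            if self.ref_aln[i] != self.query_aln[i]:
                out.append(p)
            if self.ref_aln[i] != GAP:
                p += 1
        return sorted(set(out))


def _interval_gap(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> int:
    """Nucleotides strictly between two intervals; 0 if they touch/overlap."""
    if a_hi <= b_lo:
        return b_lo - a_hi
    if b_hi <= a_lo:
        return a_lo - b_hi
    return 0


def find_tsm(
    ref: str,
    query: str,
    min_copied: int = 6,
    max_dist: int = 8,
    min_explained: int = 1,
    max_copied: int = 60,
    alignment: Optional[tuple[str, str]] = None,
) -> list[TSMEvent]:
    """Enumerate all admissible TSM events explaining parent/child differences.

    The child segment aligned to the target columns must equal the reverse
    complement of the parent source segment exactly; the copied length must
    be at least ``min_copied`` (and at most ``max_copied``, a cap motivated
    by local, hairpin-scale events), the gap between source and target
    intervals at most ``max_dist``, and the event must remove at least
    ``min_explained`` aligned differences.  Events are ranked by explained
    differences (desc), copied length (asc), then leftmost coordinates.
    """
    if not ref or not query:
        return []
    if alignment is None:
        if len(ref) == len(query):
            alignment = (ref, query)  # identity alignment
        else:
            alignment = pairwise_align(ref, query)
    ap = _AlignedPair(*alignment)
    if ap.ref != ref or ap.query != query:
        raise ValueError("alignment does not match the provided sequences")

    m = len(ref)
    events: list[TSMEvent] = []
    seen: set[tuple[int, int, int, int]] = set()

    # candidate target windows must overlap at least one difference
    if min_explained > 0:
        diff_pos = ap.diff_parent_positions()
        if not diff_pos:
            return []
        p1_candidates = sorted(
            {p for d in diff_pos for p in range(max(0, d - max_copied), d + 1)}
        )
    else:
        p1_candidates = list(range(m + 1))

    for p1 in p1_candidates:
        for p4 in range(p1, min(m, p1 + max_copied) + 1):
            c1, c4 = ap.child_segment(p1, p4)
            L = c4 - c1
            if L < min_copied or L > max_copied:
                continue
            explained = ap.diffs_in(p1, p4)
            if explained < min_explained:
                continue
            needle = reverse_complement(query[c1:c4])
            lo = max(0, p1 - max_dist - L)
            hi = min(m, p4 + max_dist + L)
            start = lo
            while True:
                p3 = ref.find(needle, start, hi)
                if p3 < 0:
                    break
                p2 = p3 + L
                if _interval_gap(p3, p2, p1, p4) <= max_dist:
                    key = (p1, p2, p3, p4)
                    if key not in seen:
                        seen.add(key)
                        events.append(
                            TSMEvent(
                                p1=p1,
                                p2=p2,
                                p3=p3,
                                p4=p4,
                                copied_len=L,
                                explained=explained,
                                child_target=(c1, c4),
                            )
                        )
                start = p3 + 1
    events.sort(key=TSMEvent.sort_key)
    return events


def _contains(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[0] and b[1] <= a[1]


def overlap_groups(events: list[TSMEvent]) -> list[list[TSMEvent]]:
    """Group events whose target intervals fully overlap (nest), ranked.

    Each group is one copy site; only one member of a group is counted
    downstream.  Partially overlapping targets stay in separate groups.
    """
    groups: list[list[TSMEvent]] = []
    for e in sorted(events, key=TSMEvent.sort_key):
        for group in groups:
            k = group[0]
            if _contains(k.target, e.target) or _contains(e.target, k.target):
                group.append(e)
                break
        else:
            groups.append([e])
    return groups


def dedup_overlapping(events: list[TSMEvent]) -> list[TSMEvent]:
    """Collapse fully overlapping (nested or identical) target intervals.

    Among events whose targets contain one another, only the top-ranked one
    is kept; partially overlapping targets are all kept.
    """
    return [group[0] for group in overlap_groups(events)]
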