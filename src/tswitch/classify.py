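"""Attribution of template-switch events to hairpin mutation patterns.

Implements the single-event pattern taxonomy (compensatory-mutation
categories, loop inversions, asymmetric events, stem insertions), the
detection of instantaneous compensatory mutations, and base-pair
substitution spectra.

A compensatory mutation (CM) is attributed to an event only when (1) the
source or target overlaps a parent/child sequence difference, (2) the
corrected rung bridges the source and target in separate halves of the
same stem, (3) source and target are equally distant from the loop
(rung-index-wise, ignoring bulges), and (4) the event turns an imperfect
pair into a perfect Watson-Crick pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .ancestry import AnnotatedNode
from .seqcore import GAP, WC_PAIRS, interval_columns, position_columns
from .structure import HairpinElement, extract_hairpins, has_ambiguity, parse_dotbracket
from .tsm_engine import TSMEvent

TWO_STEP = "two_step"
INSTANTANEOUS = "instantaneous"

CATEGORIES = (
    "one_cm",
    "cm_loop_inversion",
    "cm_parallel_loop",
    "multiple_cm",
    "loop_inversion_only",
    "within_stem_half",
    "loop_to_stem",
    "insertion_in_stem",
)

#: minimum explained differences per category
_MIN_EXPLAINED = {cat: 2 for cat in CATEGORIES}
_MIN_EXPLAINED["one_cm"] = 1
_MIN_EXPLAINED["insertion_in_stem"] = 1


@dataclass(frozen=True)
class CMRecord:
    """One stem rung change: parent pair -> child pair."""

    positions: tuple[int, int]  # parent ungapped coordinates of the rung
    parent_pair: str
    child_pair: str
    mode: str  # instantaneous | two_step
    #: loop interval of the hosting hairpin (parent ungapped coordinates)
    hairpin_loop: Optional[tuple[int, int]] = None


@dataclass
class PatternRecord:
    """A classified event (or an explicit drop with its reason)."""

    category: Optional[str]
    cm_count: int
    branch_type: str  # terminal | internal
    node: str  # child (query) node label
    event: TSMEvent
    cms: list[CMRecord] = field(default_factory=list)
    drop_reason: Optional[str] = None


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def _point_in(p: int, iv: tuple[int, int]) -> bool:
    return iv[0] <= p < iv[1]


def _region_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Interval overlap that also lets an empty interval sit inside b."""
    if a[0] == a[1]:
        return b[0] <= a[0] <= b[1]
    return _overlap(a, b)


def child_base_at(parent: AnnotatedNode, child: AnnotatedNode, pos: int) -> str:
    """Child character at the alignment column of parent position ``pos``."""
    col = position_columns(parent.gapped_seq)[pos]
    return child.gapped_seq[col]


def _min_rung_index(h: HairpinElement, region: tuple[int, int]) -> Optional[int]:
    """Distance from the loop of the rung nearest the loop touched by region."""
    for idx, (i, j) in enumerate(h.rungs):
        if _point_in(i, region) or _point_in(j, region):
            return idx
    return None


def _rungs_with_child(
    hairpin: HairpinElement,
    parent: AnnotatedNode,
    child: AnnotatedNode,
    child_hairpin: Optional[HairpinElement],
) -> list[tuple[int, int]]:
    """Stem rungs of the parent hairpin, completed from the child structure.

    A rung whose pair is fully broken in the parent does not appear in the
    parent's predicted structure; if the child's homologous stem pairs it,
    the rung is still part of the stem geometry and is included (mapped to
    parent coordinates through the alignment).
    """
    rungs = {r: idx for idx, r in enumerate(hairpin.rungs)}
    if child_hairpin is not None:
        ccols = position_columns(child.gapped_seq)
        col_to_ppos = {
            col: p for p, col in enumerate(position_columns(parent.gapped_seq))
        }
        for idx, (ci, cj) in enumerate(child_hairpin.rungs):
            pi = col_to_ppos.get(ccols[ci])
            pj = col_to_ppos.get(ccols[cj])
            if pi is None or pj is None:
                continue
            rungs.setdefault((pi, pj), idx)
    return sorted(rungs, key=rungs.__getitem__)


def attribute_cm(
    event: TSMEvent,
    hairpin: HairpinElement,
    parent: AnnotatedNode,
    child: AnnotatedNode,
    child_hairpin: Optional[HairpinElement] = None,
) -> list[CMRecord]:
    """Stem rungs converted from non-Watson-Crick to Watson-Crick by an event.

    Bulges and internal loops are ignored (rung indexing skips them); an
    event whose source and target are not equally distant from the loop
    attributes no CMs.
    """
    src, tgt = event.source, event.target
    # condition 1: the event must overlap an observed difference
    if event.explained < 1 and not _source_has_diff(event, parent, child):
        return []
    # condition 3: equal distance from the loop, rung-index-wise
    src_idx = _min_rung_index(hairpin, src)
    tgt_idx = _min_rung_index(hairpin, tgt)
    if src_idx is None or tgt_idx is None or src_idx != tgt_idx:
        return []
    records: list[CMRecord] = []
    pcols = position_columns(parent.gapped_seq)
    for i, j in _rungs_with_child(hairpin, parent, child, child_hairpin):
        # condition 2: the corrected rung bridges source and target in
        # separate stem halves
        bridges = (_point_in(i, src) and _point_in(j, tgt)) or (
            _point_in(i, tgt) and _point_in(j, src)
        )
        if not bridges:
            continue
        parent_pair = parent.seq[i] + parent.seq[j]
        if parent_pair in WC_PAIRS:
            continue  # condition 4: parent pair must be imperfect
        cx = child.gapped_seq[pcols[i]]
        cy = child.gapped_seq[pcols[j]]
        if cx == GAP or cy == GAP:
            continue
        child_pair = cx + cy
        if child_pair not in WC_PAIRS:
            continue  # condition 4: child pair must be perfect
        records.append(
            CMRecord(
                positions=(i, j),
                parent_pair=parent_pair,
                child_pair=child_pair,
                mode=TWO_STEP,
            )
        )
    return records


def _source_has_diff(
    event: TSMEvent, parent: AnnotatedNode, child: AnnotatedNode
) -> bool:
    cols = interval_columns(parent.gapped_seq, event.p3, event.p2)
    return any(
        parent.gapped_seq[c] != child.gapped_seq[c]
        for c in cols
    )


def _child_len_over(parent: AnnotatedNode, child: AnnotatedNode, lo: int, hi: int) -> int:
    cols = interval_columns(parent.gapped_seq, lo, hi)
    return sum(1 for c in cols if child.gapped_seq[c] != GAP)


def detect_loop_inversion(
    event: TSMEvent,
    hairpin: HairpinElement,
    parent: AnnotatedNode,
    child: AnnotatedNode,
) -> bool:
    """Loop inversion: source and target span both stem halves; loop length kept."""
    for region in (event.source, event.target):
        if not (
            _overlap(region, hairpin.left_half)
            and _overlap(region, hairpin.right_half)
        ):
            return False
    lo, hi = hairpin.loop
    return _child_len_over(parent, child, lo, hi) == hi - lo


def _loop_columns(node: AnnotatedNode, h: HairpinElement) -> tuple[int, int]:
    cols = interval_columns(node.gapped_seq, h.loop[0], h.loop[1])
    return (cols.start, cols.stop)


def structure_retained(
    hairpin: HairpinElement,
    parent: AnnotatedNode,
    child_hairpins: list[HairpinElement],
    child: AnnotatedNode,
) -> bool:
    """True iff the child keeps a hairpin whose loop occupies the same columns."""
    target = _loop_columns(parent, hairpin)
    return any(_loop_columns(child, hc) == target for hc in child_hairpins)


def _loop_diff_count(
    hairpin: HairpinElement, parent: AnnotatedNode, child: AnnotatedNode
) -> int:
    cols = interval_columns(parent.gapped_seq, hairpin.loop[0], hairpin.loop[1])
    return sum(
        1 for c in cols if parent.gapped_seq[c] != child.gapped_seq[c]
    )


def host_hairpin(
    event: TSMEvent, hairpins: list[HairpinElement]
) -> Optional[HairpinElement]:
    """The hairpin most overlapped by the event's source and target."""
    best = None
    best_ov = 0
    for h in hairpins:
        ov = 0
        for region in (event.source, event.target):
            lo = max(region[0], h.span[0])
            hi = min(region[1], h.span[1])
            ov += max(0, hi - lo)
            if region[0] == region[1] and _point_in(region[0], h.span):
                ov += 1  # empty target sitting inside the hairpin
        if ov > best_ov:
            best, best_ov = h, ov
    return best


def classify_pattern(
    event: TSMEvent,
    parent: AnnotatedNode,
    child: AnnotatedNode,
    parent_hairpins: Optional[list[HairpinElement]] = None,
    child_hairpins: Optional[list[HairpinElement]] = None,
) -> PatternRecord:
    """Assign exactly one pattern category to a quality-passing event.

    Category precedence: CM-with-loop-change categories before multiple_cm
    before one_cm; the asymmetric categories require the child to retain
    the hairpin structure.  Events matching no category are returned with
    ``category=None`` and an explicit drop reason.
    """
    if parent_hairpins is None:
        parent_hairpins = extract_hairpins(
            parse_dotbracket(parent.structure), parent.structure
        )
    if child_hairpins is None:
        child_hairpins = extract_hairpins(
            parse_dotbracket(child.structure), child.structure
        )
    branch_type = "terminal" if child.is_leaf else "internal"

    def _drop(reason: str) -> PatternRecord:
        return PatternRecord(
            category=None,
            cm_count=0,
            branch_type=branch_type,
            node=child.label,
            event=event,
            drop_reason=reason,
        )

    h = host_hairpin(event, parent_hairpins)
    if h is None:
        return _drop("outside_hairpin")

    loop_cols = _loop_columns(parent, h)
    child_match = next(
        (hc for hc in child_hairpins if _loop_columns(child, hc) == loop_cols),
        None,
    )
    cms = attribute_cm(event, h, parent, child, child_match)
    inv = detect_loop_inversion(event, h, parent, child)
    loop_diffs = _loop_diff_count(h, parent, child)
    retained = child_match is not None
    net_insert = (event.p2 - event.p3) - (event.p4 - event.p1)
    src, tgt = event.source, event.target
    exp = event.explained

    src_halves = {
        half
        for half, iv in (("L", h.left_half), ("R", h.right_half))
        if _region_overlap(src, iv)
    }
    tgt_halves = {
        half
        for half, iv in (("L", h.left_half), ("R", h.right_half))
        if _region_overlap(tgt, iv)
    }
    src_loop = _region_overlap(src, h.loop)
    tgt_loop = _region_overlap(tgt, h.loop)

    def _make(category: str) -> PatternRecord:
        return PatternRecord(
            category=category,
            cm_count=len(cms),
            branch_type=branch_type,
            node=child.label,
            event=event,
            cms=cms,
        )

    if cms and inv and exp >= _MIN_EXPLAINED["cm_loop_inversion"]:
        return _make("cm_loop_inversion")
    if cms and loop_diffs >= 1 and exp >= _MIN_EXPLAINED["cm_parallel_loop"]:
        return _make("cm_parallel_loop")
    if len(cms) >= 2 and exp >= _MIN_EXPLAINED["multiple_cm"]:
        return _make("multiple_cm")
    if len(cms) == 1 and exp >= _MIN_EXPLAINED["one_cm"]:
        return _make("one_cm")
    if inv and not cms and exp >= _MIN_EXPLAINED["loop_inversion_only"]:
        return _make("loop_inversion_only")
    if (
        net_insert > 0
        and src_halves
        and tgt_halves
        and not (src_halves & tgt_halves)
        and exp >= _MIN_EXPLAINED["insertion_in_stem"]
    ):
        return _make("insertion_in_stem")
    if (
        src_loop
        and not tgt_loop
        and len(tgt_halves) == 1
        and retained
        and exp >= _MIN_EXPLAINED["loop_to_stem"]
    ):
        return _make("loop_to_stem")
    if (
        not src_loop
        and not tgt_loop
        and len(src_halves) == 1
        and src_halves == tgt_halves
        and retained
        and exp >= _MIN_EXPLAINED["within_stem_half"]
    ):
        return _make("within_stem_half")
    return _drop("no_category")


def detect_instantaneous_cms(
    parent: AnnotatedNode,
    child: AnnotatedNode,
    parent_hairpins: Optional[list[HairpinElement]] = None,
    child_hairpins: Optional[list[HairpinElement]] = None,
    mask=None,
    grandchildren: Optional[list[AnnotatedNode]] = None,
) -> list[CMRecord]:
    """Instantaneous CMs: same-branch initial and restoring mutations.

    Qualifying hairpins have loops at identical alignment columns in parent
    and child, perfect Watson-Crick stems on both sides, no ambiguity codes
    in the reference hairpin, and (for internal children) identical-form
    inheritance of the loop by at least one of the child's own children.
    One record is emitted per rung whose pair differs; a stem may therefore
    contribute several records.
    """
    from .qc import inheritance_check, interval_in_mask
    from .structure import is_perfect_stem

    if parent_hairpins is None:
        parent_hairpins = extract_hairpins(
            parse_dotbracket(parent.structure), parent.structure
        )
    if child_hairpins is None:
        child_hairpins = extract_hairpins(
            parse_dotbracket(child.structure), child.structure
        )
    child_by_loop = {_loop_columns(child, hc): hc for hc in child_hairpins}
    pcols = position_columns(parent.gapped_seq)
    records: list[CMRecord] = []
    for hp in parent_hairpins:
        hc = child_by_loop.get(_loop_columns(parent, hp))
        if hc is None:
            continue  # loop not at identical positions
        if not is_perfect_stem(hp, parent.seq) or not is_perfect_stem(hc, child.seq):
            continue
        if has_ambiguity(parent.seq, hp.span[0], hp.span[1]):
            continue
        if mask is not None:
            cols = interval_columns(parent.gapped_seq, hp.span[0], hp.span[1])
            if not interval_in_mask(mask, cols):
                continue
        if grandchildren is not None and not child.is_leaf:
            loop_cols = interval_columns(parent.gapped_seq, hp.loop[0], hp.loop[1])
            if not inheritance_check(child, loop_cols, grandchildren):
                continue
        for i, j in hp.rungs:
            cx = child.gapped_seq[pcols[i]]
            cy = child.gapped_seq[pcols[j]]
            if cx == GAP or cy == GAP:
                continue
            parent_pair = parent.seq[i] + parent.seq[j]
            child_pair = cx + cy
            if child_pair == parent_pair:
                continue
            if child_pair in WC_PAIRS:  # parent pair is WC by the stem check
                records.append(
                    CMRecord(
                        positions=(i, j),
                        parent_pair=parent_pair,
                        child_pair=child_pair,
                        mode=INSTANTANEOUS,
                        hairpin_loop=hp.loop,
                    )
                )
    return records


@dataclass
class SpectrumResult:
    """16x16 parent-pair -> child-pair counts with the marginal shares."""

    counts: "object"  # pandas DataFrame, 16x16
    n: int
    wobble_parent_share: float  # parent pair in {GT, TG}
    wc_flip_share: float  # A-T <-> G-C or C-G <-> T-A changes


_PAIRS = [a + b for a in "ACGT" for b in "ACGT"]
_WC_FLIPS = {("AT", "GC"), ("GC", "AT"), ("CG", "TA"), ("TA", "CG")}


def substitution_spectrum(records: list[CMRecord]) -> SpectrumResult:
    """Count parent-vs-child base-pair changes for one CM mode.

    Also reports the share of records whose parent pair is a G-T/T-G wobble
    (the two-step signal) and the share of A-T <-> G-C / C-G <-> T-A changes
    (instantaneous CMs compatible with a wobble intermediate).
    """
    import pandas as pd

    modes = {r.mode for r in records}
    if len(modes) > 1:
        raise ValueError("substitution_spectrum expects records of a single mode")
    counts = pd.DataFrame(0, index=_PAIRS, columns=_PAIRS, dtype=int)
    for r in records:
        counts.loc[r.parent_pair, r.child_pair] += 1
    n = len(records)
    wobble = sum(1 for r in records if r.parent_pair in ("GT", "TG"))
    flips = sum(1 for r in records if (r.parent_pair, r.child_pair) in _WC_FLIPS)
    return SpectrumResult(
        counts=counts,
        n=n,
        wobble_parent_share=wobble / n if n else 0.0,
        wc_flip_share=flips / n if n else 0.0,
    )
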