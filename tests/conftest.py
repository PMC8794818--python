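"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache

import pytest

from tswitch.ancestry import AnnotatedNode
from tswitch.seqcore import reverse_complement
from tswitch.structure import fold_max_pairing
from tswitch.tsm_engine import TSMEvent, apply_tsm

# ---------------------------------------------------------------------------
# independent folding oracle: explicit enumeration of nested structures

_PAIRABLE = {"AT", "TA", "GC", "CG", "GT", "TG"}


@lru_cache(maxsize=32)
def enumerate_structures(n: int, min_loop: int = 3) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All nested pair sets on n positions with hairpin loops >= min_loop.

    Pure enumeration (no dynamic programming shared with the folder): the
    first position is either unpaired or paired with each admissible
    partner, recursing on the inside and outside fragments.
    """

    def rec(positions: tuple[int, ...]) -> list[tuple[tuple[int, int], ...]]:
        if not positions:
            return [()]
        first, rest = positions[0], positions[1:]
        out = [s for s in rec(rest)]
        for idx, j in enumerate(rest):
            if j - first <= min_loop:
                continue
            inside, outside = rest[:idx], rest[idx + 1 :]
            for si in rec(inside):
                for so in rec(outside):
                    out.append(((first, j),) + si + so)
        return out

    return tuple(rec(tuple(range(n))))


def oracle_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Brute-force maximum nested pairing by structure enumeration."""
    best = 0
    for struct in enumerate_structures(len(seq), min_loop):
        if all(seq[i] + seq[j] in _PAIRABLE for i, j in struct):
            best = max(best, len(struct))
    return best


# ---------------------------------------------------------------------------
# independent TSM oracle: exhaustive switch-point quadruple enumeration


def oracle_tsm_events(
    ref: str,
    query: str,
    min_copied: int = 6,
    max_dist: int = 8,
    min_explained: int = 1,
    max_copied: int = 60,
) -> set[tuple[int, int, int, int, int]]:
    """All admissible (p1, p2, p3, p4, explained) under identity alignment."""
    assert len(ref) == len(query)
    m = len(ref)
    out = set()
    for p1 in range(m + 1):
        for p4 in range(p1, m + 1):
            copied = p4 - p1
            if not min_copied <= copied <= max_copied:
                continue
            seg = query[p1:p4]
            explained = sum(a != b for a, b in zip(ref[p1:p4], seg))
            if explained < min_explained:
                continue
            need = reverse_complement(seg)
            for p3 in range(0, m - copied + 1):
                if ref[p3 : p3 + copied] != need:
                    continue
                p2 = p3 + copied
                if p2 <= p1:
                    gap = p1 - p2
                elif p3 >= p4:
                    gap = p3 - p4
                else:
                    gap = 0
                if gap <= max_dist:
                    out.add((p1, p2, p3, p4, explained))
    return out


# ---------------------------------------------------------------------------
# annotated-node builder and the six classification scenario fixtures


def annot(
    label: str,
    seq: str,
    leaf: bool = False,
    gapped: str | None = None,
    structure: str | None = None,
) -> AnnotatedNode:
    return AnnotatedNode(
        label=label,
        gapped_seq=gapped or seq,
        structure=structure if structure is not None else fold_max_pairing(seq),
        is_leaf=leaf,
    )


def scenario_fixtures() -> dict[str, tuple[AnnotatedNode, AnnotatedNode, TSMEvent]]:
    """Six constructed parent/child scenarios, one per pattern category.

    Each child is produced from its parent by ``apply_tsm`` with the listed
    switch points; the expected category is the dict key.
    """
    out = {}

    # loop inversion at a perfect hairpin (source == target spans the loop)
    parent = "GGCACGAAAGTGCC"
    child = apply_tsm(parent, 3, 11, 3, 11)
    out["loop_inversion_only"] = (
        annot("P", parent),
        annot("C", child, leaf=True),
        TSMEvent(p1=3, p2=11, p3=3, p4=11, copied_len=8, explained=4),
    )

    # single wobble fixed by an opposite-half copy
    parent = "TGGCGCGAAAGTGCCA"
    child = apply_tsm(parent, 10, 6, 0, 16)
    out["one_cm"] = (
        annot("P", parent),
        annot("C", child, leaf=True),
        TSMEvent(p1=10, p2=6, p3=0, p4=16, copied_len=6, explained=1),
    )

    # two T-G wobbles fixed at once by a full-half copy
    parent = "GGTGGTG" + "AAAA" + "CGCCGCC"
    child = apply_tsm(parent, 11, 7, 0, 18)
    out["multiple_cm"] = (
        annot("P", parent),
        annot("C", child, leaf=True),
        TSMEvent(p1=11, p2=7, p3=0, p4=18, copied_len=7, explained=2),
    )

    # copy within one stem half restoring an internal inverted repeat
    parent = "CCCCCC" + "GAGAGG" + "AAAA" + "CACCCCGGGGGG"
    child = apply_tsm(parent, 6, 6, 0, 12)
    out["within_stem_half"] = (
        annot("P", parent),
        annot("C", child, leaf=True),
        TSMEvent(p1=6, p2=6, p3=0, p4=12, copied_len=6, explained=2),
    )

    # copy from the loop region into the adjacent stem half
    parent = "GCAGCGAT" + "AGCG" + "ATCGAGGC"
    child = apply_tsm(parent, 12, 14, 8, 18)
    out["loop_to_stem"] = (
        annot("P", parent),
        annot("C", child, leaf=True),
        TSMEvent(p1=12, p2=14, p3=8, p4=18, copied_len=6, explained=2),
    )

    # insertion into the opposite stem half
    parent = "AACCAA" + "GCAGCCGCAAGGCTGC" + "AACCAA"
    child = apply_tsm(parent, 19, 12, 6, 19)
    out["insertion_in_stem"] = (
        annot("P", parent, gapped=parent[:19] + "-" * 6 + parent[19:]),
        annot("C", child, leaf=True),
        TSMEvent(
            p1=19, p2=12, p3=6, p4=19, copied_len=6, explained=6,
            child_target=(19, 25),
        ),
    )
    return out


@pytest.fixture(scope="session")
def scenarios():
    return scenario_fixtures()
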