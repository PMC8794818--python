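import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tswitch.seqcore import reverse_complement
from tswitch.tsm_engine import (
    LEFTWARD,
    RIGHTWARD,
    TSMEvent,
    apply_tsm,
    classify_jump,
    dedup_overlapping,
    find_tsm,
)

from conftest import oracle_tsm_events


class TestApplyTsm:
    def test_loop_inversion_geometry(self):
        assert apply_tsm("GGCACGAAAGTGCC", 3, 11, 3, 11) == "GGCACTTTCGTGCC"

    def test_wobble_fix_geometry(self):
        assert apply_tsm("TGGCGCGAAAGTGCCA", 10, 6, 0, 16) == "TGGCGCGAAAGCGCCA"

    def test_empty_copy_empty_target_is_identity(self):
        assert apply_tsm("ACGTACGT", 3, 5, 5, 3) == "ACGTACGT"

    def test_length_change(self):
        out = apply_tsm("AAAATTTT", 4, 6, 2, 4)
        assert out == "AAAA" + reverse_complement("AATT") + "TTTT"
        assert len(out) == 8 - 0 + 4  # empty target, four copied bases

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_tsm("ACGT", 0, 9, 0, 2)

    @given(st.text(alphabet="ACGT", min_size=8, max_size=40), st.data())
    @settings(max_examples=100, deadline=None)
    def test_self_revcomp_replacement_is_identity(self, seq, data):
        # source = target and the copy replaces a revcomp palindrome
        p1 = data.draw(st.integers(0, len(seq) - 4))
        p4 = data.draw(st.integers(p1, len(seq)))
        sub = seq[:p1] + reverse_complement(seq[p1:p4]) + seq[p4:]
        assert apply_tsm(sub, p1, p4, p1, p4)[p1:p4] == seq[p1:p4]


@pytest.mark.parametrize(
    "p1,p2,expected",
    [(10, 6, LEFTWARD), (3, 11, RIGHTWARD), (5, 5, LEFTWARD)],
)
def test_classify_jump(p1, p2, expected):
    e = TSMEvent(p1=p1, p2=p2, p3=0, p4=max(p1, p2) + 1, copied_len=6, explained=1)
    assert classify_jump(e) == expected
    assert e.jump == expected


class TestFindTsm:
    def test_wobble_fix_event(self):
        events = find_tsm("TGGCGCGAAAGTGCCA", "TGGCGCGAAAGCGCCA")
        assert [(e.p1, e.p2, e.p3, e.p4, e.explained) for e in events] == [
            (10, 6, 0, 16, 1)
        ]

    def test_identical_sequences_give_nothing(self):
        assert find_tsm("ACGT" * 10, "ACGT" * 10) == []

    def test_empty_sequences(self):
        assert find_tsm("", "") == []

    def test_loop_inversion_admissible_set_contains_planted(self):
        ref, query = "GGCACGAAAGTGCC", "GGCACTTTCGTGCC"
        events = find_tsm(ref, query)
        quads = {(e.p1, e.p2, e.p3, e.p4) for e in events}
        assert (3, 11, 3, 11) in quads
        top = dedup_overlapping(events)[0]
        assert apply_tsm(ref, top.p1, top.p2, top.p3, top.p4) == query
        assert top.explained == 4

    def test_distance_filter(self):
        # source 20 nt away from the target: beyond the distance cap
        ref = "GGGGCCC" + "A" * 20 + "TATATAT" + "A" * 5
        query = ref[:29] + reverse_complement(ref[0:7]) + ref[36:]
        assert all(
            e.p3 != 0 or e.p2 != 7 for e in find_tsm(ref, query, max_dist=8)
        )


def test_dedup_overlapping():
    def ev(p1, p4, explained, copied=6):
        return TSMEvent(p1=p1, p2=p4, p3=p1, p4=p4, copied_len=copied, explained=explained)

    a, b = ev(0, 10, 3, copied=10), ev(2, 8, 2)
    assert dedup_overlapping([a, b]) == [a]  # nested: top-ranked survives
    c = ev(20, 30, 1, copied=10)
    assert dedup_overlapping([a, c]) == [a, c]  # disjoint: both kept
    d = ev(0, 10, 3, copied=10)
    assert len(dedup_overlapping([a, d])) == 1  # identical targets collapse


class TestOracleEquivalence:
    """find_tsm agrees with exhaustive quadruple enumeration."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 41))
        ref = "".join(rng.choice(list("ACGT"), size=n))
        query = list(ref)
        for _ in range(int(rng.integers(1, 5))):
            i = int(rng.integers(n))
            query[i] = "ACGT"[int(rng.integers(4))]
        query = "".join(query)
        got = {
            (e.p1, e.p2, e.p3, e.p4, e.explained)
            for e in find_tsm(ref, query, alignment=(ref, query))
        }
        assert got == oracle_tsm_events(ref, query)


class TestRoundTrip:
    """Events applied then detected reproduce the child exactly."""

    @pytest.mark.parametrize("seed", range(10))
    def test_seeded_perturbations(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(30, 61))
        ref = "".join(rng.choice(list("ACGT"), size=n))
        copied = int(rng.integers(6, 13))
        p3 = int(rng.integers(0, n - copied + 1))
        p2 = p3 + copied
        # place the target adjacent to the source within the distance cap
        p1 = min(n, p2 + int(rng.integers(0, 9)))
        p4 = min(n, p1 + int(rng.integers(0, copied + 1)))
        child = apply_tsm(ref, p1, p2, p3, p4)
        aln = (
            ref[:p4] + "-" * copied + ref[p4:],
            ref[:p1] + "-" * (p4 - p1) + reverse_complement(ref[p3:p2]) + ref[p4:],
        )
        events = find_tsm(ref, child, alignment=aln, min_explained=0)
        assert any(
            apply_tsm(ref, e.p1, e.p2, e.p3, e.p4) == child for e in events
        )
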