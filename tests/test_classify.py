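import pytest

from tswitch.classify import (
    INSTANTANEOUS,
    TWO_STEP,
    CMRecord,
    attribute_cm,
    classify_pattern,
    detect_instantaneous_cms,
    detect_loop_inversion,
    host_hairpin,
    substitution_spectrum,
)
from tswitch.structure import extract_hairpins, parse_dotbracket
from tswitch.tsm_engine import TSMEvent, apply_tsm

from conftest import annot


def hairpins_of(node):
    return extract_hairpins(parse_dotbracket(node.structure), node.structure)


class TestAttributeCm:
    def test_wobble_fix_attributed(self, scenarios):
        parent, child, event = scenarios["one_cm"]
        (h,) = hairpins_of(parent)
        records = attribute_cm(event, h, parent, child)
        assert [(r.parent_pair, r.child_pair) for r in records] == [("GT", "GC")]
        assert records[0].positions == (4, 11)

    def test_same_half_event_attributes_nothing(self, scenarios):
        parent, child, event = scenarios["within_stem_half"]
        h = host_hairpin(event, hairpins_of(parent))
        assert attribute_cm(event, h, parent, child) == []

    def test_wc_to_wc_change_attributes_nothing(self):
        # opposite-half copy that flips A-T to T-A style content is not a CM
        parent = "TGGCGCGAAAGCGCCA"  # already perfect
        child = apply_tsm(parent, 10, 6, 0, 16)
        assert child == parent  # perfect stems are fixed points
        p, c = annot("P", parent), annot("C", child, leaf=True)
        event = TSMEvent(p1=10, p2=6, p3=0, p4=16, copied_len=6, explained=0)
        (h,) = hairpins_of(p)
        assert attribute_cm(event, h, p, c) == []

    def test_unequal_loop_distance_blocks_attribution(self, scenarios):
        parent, child, _ = scenarios["one_cm"]
        (h,) = hairpins_of(parent)
        # source shifted one rung deeper than the target
        event = TSMEvent(p1=11, p2=6, p3=0, p4=16, copied_len=6, explained=1)
        assert attribute_cm(event, h, parent, child) == []


class TestLoopInversion:
    def test_true_inversion(self, scenarios):
        parent, child, event = scenarios["loop_inversion_only"]
        (h,) = hairpins_of(parent)
        assert detect_loop_inversion(event, h, parent, child)

    def test_one_half_event_is_not_inversion(self, scenarios):
        parent, child, event = scenarios["one_cm"]
        (h,) = hairpins_of(parent)
        assert not detect_loop_inversion(event, h, parent, child)

    def test_loop_length_change_blocks_inversion(self):
        parent = "GGCACGAAAGTGCC"
        # copy one base short: the child loop loses a position
        child = apply_tsm(parent, 3, 11, 4, 11)
        assert len(child) == len(parent) - 1
        p = annot("P", parent)
        c = annot("C", child, leaf=True, gapped=child[:8] + "-" + child[8:])
        event = TSMEvent(p1=3, p2=11, p3=4, p4=11, copied_len=7, explained=4)
        (h,) = hairpins_of(p)
        assert not detect_loop_inversion(event, h, p, c)


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "category",
        [
            "one_cm",
            "loop_inversion_only",
            "multiple_cm",
            "within_stem_half",
            "loop_to_stem",
            "insertion_in_stem",
        ],
    )
    def test_scenarios(self, scenarios, category):
        parent, child, event = scenarios[category]
        record = classify_pattern(event, parent, child)
        assert record.category == category
        assert record.branch_type == "terminal"

    def test_cm_counts(self, scenarios):
        _, _, _ = scenarios["multiple_cm"]
        parent, child, event = scenarios["multiple_cm"]
        record = classify_pattern(event, parent, child)
        assert record.cm_count == 2
        parent, child, event = scenarios["one_cm"]
        assert classify_pattern(event, parent, child).cm_count == 1

    def test_cm_parallel_loop(self):
        # opposite-half copy that also rewrites the loop in passing
        parent = "TGGCGCGAAAGTGCCA"
        child = apply_tsm(parent, 6, 10, 0, 16)
        p, c = annot("P", parent), annot("C", child, leaf=True)
        event = TSMEvent(p1=6, p2=10, p3=0, p4=16, copied_len=10, explained=5)
        record = classify_pattern(event, p, c)
        assert record.category == "cm_parallel_loop"
        assert record.cm_count >= 1

    def test_event_outside_hairpins_dropped(self):
        parent = "TGGCGCGAAAGCGCCA" + "A" * 20
        p = annot("P", parent)
        c = annot("C", parent, leaf=True)
        event = TSMEvent(p1=20, p2=30, p3=22, p4=28, copied_len=8, explained=1)
        record = classify_pattern(event, p, c)
        assert record.category is None
        assert record.drop_reason == "outside_hairpin"


class TestInstantaneousCms:
    def test_single_rung_change(self):
        p = annot("P", "TGGCGCGAAAGCGCCA")
        c = annot("C", "TGACGCGAAAGCGTCA", leaf=True)
        records = detect_instantaneous_cms(p, c)
        assert [(r.positions, r.parent_pair, r.child_pair) for r in records] == [
            ((2, 13), "GC", "AT")
        ]

    def test_identical_nodes(self):
        p = annot("P", "TGGCGCGAAAGCGCCA")
        c = annot("C", "TGGCGCGAAAGCGCCA", leaf=True)
        assert detect_instantaneous_cms(p, c) == []

    def test_wobble_in_child_blocks(self):
        p = annot("P", "TGGCGCGAAAGCGCCA")
        c = annot("C", "TGGCGCGAAAGTGCCA", leaf=True)  # child has G-T rung
        assert detect_instantaneous_cms(p, c) == []

    def test_ambiguity_in_reference_blocks(self):
        p = annot("P", "TGGCGCGAARGCGCCA", structure="((((((....))))))")
        c = annot("C", "TGACGCGAAAGCGTCA", leaf=True)
        assert detect_instantaneous_cms(p, c) == []

    def test_direction_flips_under_swap(self):
        a = annot("A", "TGGCGCGAAAGCGCCA")
        b = annot("B", "TGACGCGAAAGCGTCA", leaf=True)
        fwd = detect_instantaneous_cms(a, b)
        rev = detect_instantaneous_cms(b, a)
        assert [(r.positions, r.parent_pair) for r in fwd] == [
            (p, c)
            for (p, _), c in zip(
                [(r.positions, r.parent_pair) for r in rev],
                [r.child_pair for r in rev],
            )
        ]


class TestSpectrum:
    def test_counts_and_wobble_share(self):
        records = [
            CMRecord((0, 9), "GT", "GC", TWO_STEP) for _ in range(3)
        ]
        spec = substitution_spectrum(records)
        assert spec.counts.loc["GT", "GC"] == 3
        assert spec.wobble_parent_share == 1.0

    def test_empty(self):
        spec = substitution_spectrum([])
        assert spec.n == 0
        assert int(spec.counts.values.sum()) == 0

    def test_wc_flip_share(self):
        records = [CMRecord((0, 9), "GC", "AT", INSTANTANEOUS)]
        assert substitution_spectrum(records).wc_flip_share == 1.0

    def test_mixed_modes_rejected(self):
        records = [
            CMRecord((0, 9), "GT", "GC", TWO_STEP),
            CMRecord((0, 9), "GC", "AT", INSTANTANEOUS),
        ]
        with pytest.raises(ValueError):
            substitution_spectrum(records)
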