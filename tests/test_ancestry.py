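import itertools

import pytest

from tswitch.ancestry import (
    branch_level,
    fitch_reconstruct,
    iter_parent_child,
    load_tree,
    node_label,
    normalized_level_counts,
)


def labels(pairs):
    return [(node_label(a), node_label(b)) for a, b in pairs]


class TestIterParentChild:
    def test_balanced_quartet(self):
        t = load_tree("((A:1,B:1)X:1,(C:1,D:1)Y:1)R;", from_path=False)
        assert labels(iter_parent_child(t)) == [
            ("X", "A"), ("X", "B"), ("Y", "C"), ("Y", "D")
        ]

    def test_single_cherry_under_root_has_no_pairs(self):
        t = load_tree("(A:1,B:1)R;", from_path=False)
        assert labels(iter_parent_child(t)) == []

    def test_caterpillar(self):
        t = load_tree("(((A,B)N1,C)N2,D)R;", from_path=False)
        assert len(labels(iter_parent_child(t))) == 4


class TestBranchLevel:
    def test_cherry_parent(self):
        t = load_tree("((A,B)X,C)R;", from_path=False)
        levels = branch_level(t)
        assert levels["A"] == 0 and levels["X"] == 1

    def test_lowest_possible_level(self):
        # X has children at levels 0 (E) and 3 (deep caterpillar)
        t = load_tree("(((((A,B)N1,C)N2,D)N3,E)X,F)R;", from_path=False)
        levels = branch_level(t)
        assert levels["N3"] == 1 + min(levels["N2"], levels["D"])
        assert levels["X"] == 1  # min(child levels) + 1, not max

    def test_invariant_under_child_order(self):
        a = branch_level(load_tree("((A,B)X,(C,(D,E)Y)Z)R;", from_path=False))
        b = branch_level(load_tree("(((D,E)Y,C)Z,(B,A)X)R;", from_path=False))
        assert a == b


class TestFitch:
    def test_identical_leaves(self):
        t = load_tree("((A,B)X,C)R;", from_path=False)
        anc = fitch_reconstruct(t, {"A": "ACG", "B": "ACG", "C": "ACG"})
        assert anc == {"X": "ACG", "R": "ACG"}

    def test_three_leaf_triplet(self):
        t = load_tree("((A:1,B:1)X:1,C:1)R;", from_path=False)
        anc = fitch_reconstruct(t, {"A": "A", "B": "G", "C": "A"})
        assert anc["R"] == "A"

    def test_cherry_intersection(self):
        t = load_tree("((A,B)X,(C,D)Y)R;", from_path=False)
        anc = fitch_reconstruct(t, {"A": "C", "B": "C", "C": "G", "D": "T"})
        assert anc["X"] == "C"

    def test_gap_as_fifth_state(self):
        t = load_tree("((A,B)X,C)R;", from_path=False)
        anc = fitch_reconstruct(t, {"A": "-", "B": "-", "C": "A"})
        assert anc["X"] == "-"

    @pytest.mark.parametrize("newick", ["((A,B)X,C)R;", "((A,B)X,(C,D)Y)R;"])
    def test_minimizes_changes_vs_exhaustive(self, newick):
        """Fitch assignments reach the exhaustive minimum change count."""
        t = load_tree(newick, from_path=False)
        leaves = [node_label(n) for n in t.leaf_node_iter()]
        internals = [
            node_label(n) for n in t.preorder_node_iter() if not n.is_leaf()
        ]
        edges = [
            (node_label(n.parent_node), node_label(n))
            for n in t.preorder_node_iter()
            if n.parent_node is not None
        ]
        for assignment in itertools.product("ACG", repeat=len(leaves)):
            leaf_states = dict(zip(leaves, assignment))
            anc = fitch_reconstruct(t, leaf_states)
            states = {**leaf_states, **anc}
            cost = sum(states[a] != states[b] for a, b in edges)
            best = min(
                sum(
                    ({**leaf_states, **dict(zip(internals, combo))}[a]
                     != {**leaf_states, **dict(zip(internals, combo))}[b])
                    for a, b in edges
                )
                for combo in itertools.product("ACGT", repeat=len(internals))
            )
            assert cost == best


class TestNormalizedLevelCounts:
    def test_terminal_rate(self):
        trees = {
            "t1": load_tree("((((A,B)N1,C)N2,D)N3,(E,F)N4)R;", from_path=False),
        }
        # 6 terminal branches in the affected tree; 3 events at level 0
        records = [("t1", "A"), ("t1", "B"), ("t1", "E")]
        rates = normalized_level_counts(records, trees)
        assert rates[0] == pytest.approx(3 / 6)

    def test_unaffected_tree_excluded(self):
        trees = {
            "t1": load_tree("((A,B)X,C)R;", from_path=False),
            "t2": load_tree("((D,E)Y,F)S;", from_path=False),
        }
        rates = normalized_level_counts([("t1", "A")], trees)
        assert rates[0] == pytest.approx(1 / 3)  # only t1's terminals count

    def test_zero_events_level(self):
        trees = {"t1": load_tree("((A,B)X,C)R;", from_path=False)}
        rates = normalized_level_counts([("t1", "A")], trees)
        assert rates[1] == 0.0  # X has a branch but no events

    def test_empty_records(self):
        assert normalized_level_counts([], {}) == {}
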