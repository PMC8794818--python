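import numpy as np
import pytest

from tswitch.ancestry import node_label
from tswitch.seqcore import GAP, reverse_complement
from tswitch.structure import extract_hairpins, fold_max_pairing, parse_dotbracket
from tswitch.synthetic_data import (
    LayoutError,
    SimConfig,
    annotate_structures,
    generate_cluster,
    generate_root,
    generate_tree,
    null_evolve,
    null_replicates,
)


def small_cfg(**kw):
    base = dict(seed=0, n_leaves=8, root_length=300, n_hairpins=2)
    base.update(kw)
    return SimConfig(**base)


class TestGenerateRoot:
    def test_single_hairpin_island_folds_as_designed(self):
        cfg = SimConfig(seed=1, root_length=60, n_hairpins=1,
                        stem_len=(6, 6), kind_mix=("one_cm",))
        rng = np.random.default_rng(1)
        seq, db, (lay,) = generate_root(cfg, rng)
        a, b = lay.span
        island = seq[a:b]
        stem = lay.left[1] - lay.left[0]
        loop = lay.loop[1] - lay.loop[0]
        assert fold_max_pairing(island) == "(" * stem + "." * loop + ")" * stem

    def test_full_root_fold_recovers_every_hairpin(self):
        for seed in range(4):
            cfg = SimConfig(seed=seed, root_length=500)
            rng = np.random.default_rng(seed)
            seq, db, layouts = generate_root(cfg, rng)
            fold = fold_max_pairing(seq, max_span=100)
            loops = {
                h.loop for h in extract_hairpins(parse_dotbracket(fold), fold)
            }
            for lay in layouts:
                assert (lay.loop[0], lay.loop[1]) in loops

    def test_zero_hairpins_fold_all_dots(self):
        cfg = SimConfig(seed=0, root_length=80, n_hairpins=0, plant_events=0)
        rng = np.random.default_rng(0)
        seq, db, layouts = generate_root(cfg, rng)
        assert layouts == [] and db == "." * len(seq)
        assert fold_max_pairing(seq) == "." * len(seq)

    def test_infeasible_layout_rejected(self):
        cfg = SimConfig(seed=0, root_length=30, n_hairpins=3)
        with pytest.raises(LayoutError):
            generate_root(cfg, np.random.default_rng(0))

    def test_stems_are_reverse_complementary(self):
        cfg = small_cfg()
        rng = np.random.default_rng(5)
        seq, _, layouts = generate_root(cfg, rng)
        for lay in layouts:
            left = seq[lay.left[0] : lay.left[1]]
            right = seq[lay.right[0] : lay.right[1]]
            assert right == reverse_complement(left)


class TestEvolution:
    def test_zero_rates_give_identical_nodes(self):
        cfg = small_cfg(indel_rate=0.0, plant_events=0)
        rng = np.random.default_rng(3)
        tree = generate_tree(cfg, rng)
        for node in tree.preorder_node_iter():
            if node.edge is not None:
                node.edge.length = 0.0
        root, _, _ = generate_root(cfg, np.random.default_rng(3))
        seqs = null_evolve(tree, root, cfg, np.random.default_rng(3))
        assert all(s == root for s in seqs.values())

    def test_substitution_rate_matches_branch_length(self):
        cfg = SimConfig(seed=0, n_leaves=2, root_length=0, n_hairpins=0,
                        plant_events=0, indel_rate=0.0, gamma_shape=1e9)
        rng = np.random.default_rng(0)
        tree = generate_tree(cfg, rng)
        for node in tree.preorder_node_iter():
            if node.edge is not None:
                node.edge.length = 0.1
        root = "".join(np.random.default_rng(1).choice(list("ACGT"), size=10000))
        seqs = null_evolve(tree, root, cfg, np.random.default_rng(2))
        leaf = next(s for k, s in seqs.items() if k.startswith("L"))
        diffs = sum(a != b for a, b in zip(root, leaf))
        # expected divergence p = 3/4 (1 - exp(-4/3 t)) under equal rates
        t = 0.1
        p = 0.75 * (1 - np.exp(-4 * t / 3))
        sd = np.sqrt(p * (1 - p) * 10000)
        assert abs(diffs - p * 10000) < 4 * sd

    def test_negative_branch_rejected(self):
        cfg = small_cfg()
        rng = np.random.default_rng(0)
        tree = generate_tree(cfg, rng)
        next(tree.preorder_node_iter()).child_nodes()[0].edge.length = -0.5
        with pytest.raises(ValueError):
            null_evolve(tree, "ACGT" * 50, cfg, rng)


class TestGenerateCluster:
    def test_deterministic_given_seed(self):
        a = generate_cluster(small_cfg())
        b = generate_cluster(small_cfg())
        assert a.alignment == b.alignment
        assert a.newick == b.newick
        assert a.truth == b.truth
        assert a.structures == b.structures

    def test_leaf_count(self):
        fx = generate_cluster(small_cfg(n_leaves=10, root_length=400, n_hairpins=3))
        assert len(fx.leaf_labels()) == 10
        assert len(fx.alignment) == 2 * 10 - 1

    def test_alignment_is_rectangular(self):
        fx = generate_cluster(small_cfg())
        lengths = {len(s) for s in fx.alignment.values()}
        assert len(lengths) == 1

    def test_truth_events_replay_on_parent_sequences(self):
        """Planted switch points reproduce the child inside the event region."""
        from tswitch.tsm_engine import apply_tsm

        checked = 0
        for seed in range(4):
            fx = generate_cluster(SimConfig(seed=seed, root_length=500))
            for t in fx.truth:
                parent = fx.alignment[t.parent].replace(GAP, "")
                child = fx.alignment[t.child].replace(GAP, "")
                applied = apply_tsm(parent, t.p1, t.p2, t.p3, t.p4)
                lo = t.p1 - 1
                hi = t.p1 + (t.p2 - t.p3) + 1
                shift = len(child) - len(applied)
                assert applied[lo:hi] in child
                checked += 1
        assert checked >= 6

    def test_plant_rate_zero_gives_no_truth(self):
        fx = generate_cluster(small_cfg(plant_events=0, plant_instant_cms=0))
        assert fx.truth == [] and fx.instant_truth == []

    def test_planted_instant_cms_are_detected(self):
        from tswitch.pipeline import PipelineConfig, analyze_cluster

        found = total = 0
        for seed in range(4):
            fx = generate_cluster(
                small_cfg(seed=seed, plant_events=0, plant_instant_cms=2,
                          root_length=400, n_hairpins=3)
            )
            res = analyze_cluster(
                fx.alignment, fx.tree, PipelineConfig(), structures=fx.structures
            )
            nodes = {node for node, _ in res.instant_cms}
            for _, child, _ in fx.instant_truth:
                total += 1
                found += child in nodes
        assert total >= 6
        assert found / total >= 0.8

    def test_structure_annotation_matches_sequences(self):
        fx = generate_cluster(small_cfg())
        for label, db in fx.structures.items():
            seq = fx.alignment[label].replace(GAP, "")
            assert len(db) == len(seq)
            parse_dotbracket(db)  # balanced


class TestNullReplicates:
    def test_replicates_have_structure_and_no_truth(self):
        fx = generate_cluster(small_cfg())
        reps = null_replicates(fx, 2, seed=9)
        assert len(reps) == 2
        for rep in reps:
            assert rep.truth == []
            assert set(rep.alignment) == set(fx.alignment)
            assert rep.structures

    def test_deterministic(self):
        fx = generate_cluster(small_cfg())
        a = null_replicates(fx, 2, seed=9)
        b = null_replicates(fx, 2, seed=9)
        assert a[0].alignment == b[0].alignment

    def test_gamma_rate_heterogeneity_moment(self):
        """Per-site substitution counts overdisperse as 1/shape grows."""
        cfg = SimConfig(seed=0, n_leaves=2, root_length=0, n_hairpins=0,
                        plant_events=0, indel_rate=0.0, gamma_shape=0.25)
        rng = np.random.default_rng(0)
        tree = generate_tree(cfg, rng)
        for node in tree.preorder_node_iter():
            if node.edge is not None:
                node.edge.length = 0.3
        root = "".join(np.random.default_rng(1).choice(list("ACGT"), size=20000))
        seqs = null_evolve(tree, root, cfg, np.random.default_rng(2))
        leaf = next(s for k, s in seqs.items() if k.startswith("L"))
        diffs = sum(a != b for a, b in zip(root, leaf))
        # strong rate variation concentrates changes on fast sites, so the
        # observed difference count falls well below the homogeneous rate
        hom = 0.75 * (1 - np.exp(-4 * 0.3 / 3)) * 20000
        assert diffs < 0.9 * hom
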