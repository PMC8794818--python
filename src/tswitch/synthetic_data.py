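"""Synthetic sequence clusters with planted template-switch events.

The generator emulates the statistical shape of closely related structural
RNA gene clusters: a root sequence carrying perfect hairpins (stems of
5-12 bp closed by 3-8 nt loops, loop sequences biased toward the GNRA
family) separated by unstructured spacers, evolved down a random rooted
tree under a GTR+gamma substitution model with rare indels, plus planted
TSM events with a truth table.  Spacers are drawn from a pairing-poor
base distribution (A/C-rich) so that the planted hairpins dominate the
base-pair-maximisation fold, as the unstructured-spacer design intends.

The same machinery without planting (and rooted on a randomly selected
terminal sequence) provides the null replicates for the enrichment test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy import stats as sps

from .ancestry import load_tree, node_label
from .seqcore import GAP, reverse_complement, write_fasta

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

#: planting kinds and the pattern category each is meant to realise
PLANT_KINDS = (
    "loop_inversion",
    "one_cm",
    "multiple_cm",
    "within_stem_half",
    "insertion_in_stem",
)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cluster."""

    n_leaves: int = 10
    root_length: int = 1000
    n_hairpins: int = 3
    stem_len: tuple[int, int] = (5, 12)
    loop_len: tuple[int, int] = (3, 8)
    gnra_weight: float = 0.5
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # GTR exchangeabilities in the order AC, AG, AT, CG, CT, GT
    gtr_rates: tuple[float, ...] = (1.0, 2.0, 1.0, 1.0, 2.0, 1.0)
    gamma_shape: float = 1.0
    gamma_categories: int = 4
    branch_length_mean: float = 0.02
    #: single indel rate per site per unit branch length; the separate
    #: insertion and deletion rates are this divided by two
    indel_rate: float = 0.002
    indel_mean_len: float = 3.0
    protect_hairpins: bool = True
    #: spacer base distribution (A, C, G, T); poly-A spacers cannot pair
    #: the pyrimidine/purine stem halves or the purine loops, keeping the
    #: planted hairpins the unique fold optimum at the root
    spacer_freqs: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    plant_events: int = 3
    kind_mix: tuple[str, ...] = PLANT_KINDS
    #: instantaneous compensatory mutations planted per cluster: one rung
    #: flipped from one Watson-Crick pair to another on a single branch
    plant_instant_cms: int = 1
    seed: int = 0


@dataclass(frozen=True)
class TruthRecord:
    """One planted event, in the coordinates of the branch's parent node."""

    parent: str
    child: str
    kind: str
    p1: int
    p2: int
    p3: int
    p4: int
    hairpin: int


@dataclass
class HairpinLayout:
    """Column intervals of one planted hairpin (alignment coordinates)."""

    left: tuple[int, int]
    loop: tuple[int, int]
    right: tuple[int, int]
    #: left half built as s1 + revcomp(s1) (a within-half TSM planting site)
    palindromic: bool = False
    #: columns created by a planted insertion (bulge in the carrier subtree)
    inserted: set[int] = field(default_factory=set)

    @property
    def span(self) -> tuple[int, int]:
        return (self.left[0], self.right[1])

    def shift(self, at: int, by: int) -> None:
        def mv(iv):
            return tuple(x + by if x >= at else x for x in iv)

        self.left = mv(self.left)
        self.loop = mv(self.loop)
        self.right = mv(self.right)
        self.inserted = {c + by if c >= at else c for c in self.inserted}


@dataclass
class ClusterFixture:
    """A synthetic cluster: tree, aligned node sequences, and truth table.

    ``structures`` carries the per-node dot-bracket annotation derived from
    the planted hairpin layout (the synthetic analog of structures computed
    by an external folder); the pipeline consumes it through its
    precomputed-structure input path.
    """

    tree: dendropy.Tree
    newick: str
    alignment: dict[str, str]
    truth: list[TruthRecord]
    hairpins: list[HairpinLayout]
    config: SimConfig
    structures: dict[str, str] = field(default_factory=dict)
    #: planted instantaneous CMs as (parent, child, hairpin index) triples
    instant_truth: list[tuple[str, str, int]] = field(default_factory=list)

    def leaf_labels(self) -> list[str]:
        return [node_label(n) for n in self.tree.leaf_node_iter()]


class LayoutError(ValueError):
    """Raised when the requested hairpin layout cannot fit the root length."""


# ---------------------------------------------------------------------------
# tree and root generation


def generate_tree(cfg: SimConfig, rng: np.random.Generator) -> dendropy.Tree:
    """Random rooted binary tree by sequential joins, exponential lengths."""
    items = [f"L{i}" for i in range(cfg.n_leaves)]
    newicks = {name: name for name in items}
    nxt = 0
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[i], items[j]
        la, lb = rng.exponential(cfg.branch_length_mean, size=2) + 1e-4
        label = f"N{nxt}"
        nxt += 1
        newicks[label] = f"({newicks[a]}:{la:.6f},{newicks[b]}:{lb:.6f}){label}"
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [label]
    return load_tree(newicks[items[0]] + ";", from_path=False)


def _sample_loop(
    cfg: SimConfig, rng: np.random.Generator, palindromic: bool = False
) -> str:
    """Loop sampler over the purine alphabet, biased toward GNRA.

    Loops are drawn from {G, A} with positions beyond the third fixed to A
    (automatically true for GNRA tetraloops).  Together with pyrimidine
    left stem halves this makes the planted hairpin the unique maximum of
    the base-pair-maximisation fold: loop bases cannot pair the stems.
    """
    if palindromic:
        # adenine loop: inert against the C/G homopolymer inverted repeat
        length = int(rng.integers(cfg.loop_len[0], cfg.loop_len[1] + 1))
        return "A" * length
    if rng.random() < cfg.gnra_weight:
        return "G" + str(rng.choice(["G", "A"])) + str(rng.choice(["G", "A"])) + "A"
    length = int(rng.integers(cfg.loop_len[0], cfg.loop_len[1] + 1))
    chars = [str(rng.choice(["G", "A"])) for _ in range(min(3, length))]
    chars += ["A"] * max(0, length - 3)
    return "".join(chars)


def _sample_left_half(
    stem: int, rng: np.random.Generator, palindromic: bool
) -> str:
    """Pyrimidine left half; the right half (its reverse complement) is purine.

    A {C,T} left half cannot pair internally, with the loop, or with the
    A/C-rich spacers, so the designed cross-stem pairing is forced.  The
    closing rung and the rungs used for two-step CM planting are fixed to
    C-G so a single C->T substitution creates a T-G wobble.
    """
    if palindromic:
        # C/G homopolymer inverted repeat: s1 + revcomp(s1); the unique
        # full-size nested matching is the designed cross-stem pairing
        s1 = "C" * (stem // 2)
        return s1 + reverse_complement(s1)
    left = list(rng.choice(list("CT"), size=stem))
    left[-1] = "C"
    left[-2] = "C"
    if stem >= 4:
        left[-4] = "C"
    return "".join(left)


def generate_root(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, str, list[HairpinLayout]]:
    """Root sequence with planted hairpins, its dot-bracket, and the layout."""
    wants_palindromic = "within_stem_half" in cfg.kind_mix and cfg.n_hairpins > 0
    hairpin_parts = []
    for h in range(cfg.n_hairpins):
        palindromic = wants_palindromic and h == cfg.n_hairpins - 1
        stem = int(rng.integers(cfg.stem_len[0], cfg.stem_len[1] + 1))
        if palindromic:
            stem = max(12, stem - stem % 2)
        left = _sample_left_half(stem, rng, palindromic)
        loop = _sample_loop(cfg, rng, palindromic)
        hairpin_parts.append((left, loop, reverse_complement(left)))
    total_hp = sum(len(a) + len(b) + len(c) for a, b, c in hairpin_parts)
    spacer_total = cfg.root_length - total_hp
    n_gaps = cfg.n_hairpins + 1
    if spacer_total < 10 * n_gaps:
        raise LayoutError(
            f"root_length {cfg.root_length} too short for {cfg.n_hairpins} hairpins"
        )
    cuts = np.sort(rng.integers(0, spacer_total + 1, size=n_gaps - 1)) if n_gaps > 1 else []
    bounds = [0, *cuts, spacer_total]
    spacer_lens = [int(bounds[i + 1] - bounds[i]) for i in range(n_gaps)]
    # spacers stay wider than the maximum source-target distance so one
    # hairpin can never serve as the copy source for its neighbour
    spacer_lens = [max(12, s) for s in spacer_lens]

    def spacer(n):
        return "".join(rng.choice(list(_BASES), size=n, p=cfg.spacer_freqs))

    seq_parts = []
    db_parts = []
    layouts = []
    pos = 0
    for h in range(cfg.n_hairpins):
        sp = spacer(spacer_lens[h])
        seq_parts.append(sp)
        db_parts.append("." * len(sp))
        pos += len(sp)
        left, loop, right = hairpin_parts[h]
        layouts.append(
            HairpinLayout(
                left=(pos, pos + len(left)),
                loop=(pos + len(left), pos + len(left) + len(loop)),
                right=(
                    pos + len(left) + len(loop),
                    pos + len(left) + len(loop) + len(right),
                ),
                palindromic=wants_palindromic and h == cfg.n_hairpins - 1,
            )
        )
        seq_parts.extend([left, loop, right])
        db_parts.extend(["(" * len(left), "." * len(loop), ")" * len(right)])
        pos += len(left) + len(loop) + len(right)
    sp = spacer(spacer_lens[-1])
    seq_parts.append(sp)
    db_parts.append("." * len(sp))
    return "".join(seq_parts), "".join(db_parts), layouts


# ---------------------------------------------------------------------------
# substitution model


def _gtr_matrix(cfg: SimConfig) -> np.ndarray:
    pi = np.asarray(cfg.base_freqs, dtype=float)
    pi = pi / pi.sum()
    ex = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for (i, j), r in zip(pairs, cfg.gtr_rates):
        ex[i, j] = ex[j, i] = r
    q = ex * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    return q / scale


def _gamma_category_rates(shape: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability discrete gamma categories (mean 1)."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    edges = sps.gamma.ppf(np.linspace(0, 1, k + 1), shape, scale=1.0 / shape)
    upper = sps.gamma.cdf(edges, shape + 1, scale=1.0 / shape)
    rates = k * np.diff(upper)
    return rates / rates.mean() * 1.0


class _Evolver:
    """Per-branch substitution/indel engine over a shared column registry."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.q = _gtr_matrix(cfg)
        self.cat_rates = _gamma_category_rates(cfg.gamma_shape, cfg.gamma_categories)

    def transition_matrices(self, t: float) -> np.ndarray:
        return np.stack(
            [expm(self.q * t * r) for r in self.cat_rates], axis=0
        ).cumsum(axis=2)

    def substitute(
        self, chars: list[str], cats: list[int], t: float
    ) -> list[str]:
        pmats = self.transition_matrices(t)
        out = chars[:]
        idx = [i for i, c in enumerate(chars) if c != GAP]
        if not idx:
            return out
        codes = np.array([_CODE[chars[i]] for i in idx])
        cat = np.array([cats[i] for i in idx])
        u = self.rng.random(len(idx))
        for k in range(self.cfg.gamma_categories):
            for b in range(4):
                sel = np.nonzero((cat == k) & (codes == b))[0]
                if sel.size == 0:
                    continue
                new = np.searchsorted(pmats[k, b], u[sel], side="right")
                new = np.minimum(new, 3)
                for s, nb in zip(sel, new):
                    out[idx[s]] = _BASES[nb]
        return out

    def indel_sites(self, n_bases: int, t: float) -> int:
        lam = 0.5 * self.cfg.indel_rate * t * n_bases
        return int(self.rng.poisson(lam))

    def indel_length(self) -> int:
        p = 1.0 / self.cfg.indel_mean_len
        return min(int(self.rng.geometric(p)), 10)


def _ungapped_positions(chars: list[str]) -> list[int]:
    return [i for i, c in enumerate(chars) if c != GAP]


def _col_to_pos(chars: list[str], col: int) -> int:
    """Ungapped position of (or boundary at) an alignment column."""
    return sum(1 for c in chars[:col] if c != GAP)


@dataclass
class _PlantPlan:
    kind: str
    hairpin: int
    parent: str  # branch parent (reference node)
    child: str  # branch child (query node)
    intermediate: Optional[str] = None  # node receiving the breaking mutations
    #: second, earlier intermediate so breaking mutations are spread over
    #: two branches and stay below the sliding-window quality thresholds
    intermediate2: Optional[str] = None
    rungs: tuple[int, ...] = ()  # rung distances from the loop to break/fix


def _plan_events(
    cfg: SimConfig,
    tree: dendropy.Tree,
    layouts: list[HairpinLayout],
    rng: np.random.Generator,
) -> list[_PlantPlan]:
    """Assign each planted event a kind, a hairpin, and an eligible branch."""
    root = tree.seed_node
    edges = []  # (parent_label, child_label, grandparent_label | None)
    for node in tree.preorder_node_iter():
        if node is root or node.is_leaf():
            continue
        gp = node.parent_node
        gp_label = None if gp is root else node_label(gp)
        for child in node.child_nodes():
            edges.append((node_label(node), node_label(child), gp_label))
    if not edges or cfg.n_hairpins == 0:
        return []
    stem_len = {
        h: layouts[h].left[1] - layouts[h].left[0] for h in range(len(layouts))
    }
    palindromic = {h: layouts[h].palindromic for h in range(len(layouts))}
    loop_len = {
        h: layouts[h].loop[1] - layouts[h].loop[0] for h in range(len(layouts))
    }
    plans: list[_PlantPlan] = []
    used_hairpins: set[int] = set()
    used_edges: set[int] = set()
    # rotate the kind mix per cluster so every kind appears across a study
    offset = int(rng.integers(len(cfg.kind_mix)))
    kinds = [
        cfg.kind_mix[(offset + i) % len(cfg.kind_mix)]
        for i in range(cfg.plant_events)
    ]
    order = [int(x) for x in rng.permutation(len(edges))]
    for kind in kinds:
        feasible = [
            h
            for h in range(cfg.n_hairpins)
            if h not in used_hairpins
            and (stem_len[h] >= 6 or kind == "insertion_in_stem")
            and (kind != "insertion_in_stem" or loop_len[h] <= 7)
            and (kind != "within_stem_half" or palindromic[h])
            and (kind == "within_stem_half" or not palindromic[h])
        ]
        pick = None
        for e in order:
            if e in used_edges:
                continue
            # within-half planting spreads its mutations over two ancestor
            # branches and therefore needs a nonroot grandparent
            if kind == "within_stem_half" and edges[e][2] is None:
                continue
            pick = e
            break
        if not feasible or pick is None:
            continue  # no feasible site: skipped (logged by the caller)
        h = feasible[0]
        used_edges.add(pick)
        parent_label, child_label, gp_label = edges[pick]
        inter = inter2 = None
        rungs: tuple[int, ...] = ()
        if kind == "one_cm":
            inter, rungs = parent_label, (1,)
        elif kind == "multiple_cm":
            inter, rungs = parent_label, (1, 3)
        elif kind == "within_stem_half":
            inter, inter2 = parent_label, gp_label
        plans.append(
            _PlantPlan(
                kind=kind,
                hairpin=h,
                parent=parent_label,
                child=child_label,
                intermediate=inter,
                intermediate2=inter2,
                rungs=rungs,
            )
        )
        used_hairpins.add(h)
    # instantaneous CMs: same-branch initial + restoring substitution at
    # the outermost rung of an otherwise untouched hairpin
    for _ in range(cfg.plant_instant_cms):
        free = [h for h in range(cfg.n_hairpins) if h not in used_hairpins]
        pick = next((e for e in order if e not in used_edges), None)
        if not free or pick is None:
            break
        used_edges.add(pick)
        used_hairpins.add(free[0])
        parent_label, child_label, _ = edges[pick]
        plans.append(
            _PlantPlan(
                kind="instant_cm",
                hairpin=free[0],
                parent=parent_label,
                child=child_label,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# cluster simulation


class _Simulator:
    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.engine = _Evolver(cfg, rng)
        self.sequences: dict[str, list[str]] = {}
        self.cats: list[int] = []
        self.layouts: list[HairpinLayout] = []
        self.truth: list[TruthRecord] = []
        self.instant_cms: list[tuple[str, str, int]] = []
        self.skipped: list[str] = []

    # -- column registry -------------------------------------------------
    def _insert_columns(self, at: int, chars: dict[str, list[str]]) -> None:
        width = len(next(iter(chars.values())))
        for label, seq in self.sequences.items():
            # in place: other references to these lists must stay valid
            seq[at:at] = chars.get(label, [GAP] * width)
        self.cats[at:at] = list(
            self.rng.integers(0, self.cfg.gamma_categories, size=width)
        )
        for layout in self.layouts:
            layout.shift(at, width)

    def _protected(self) -> set[int]:
        cols: set[int] = set()
        if self.cfg.protect_hairpins:
            for layout in self.layouts:
                a, b = layout.span
                cols.update(range(max(0, a - 2), b + 2))
        return cols

    # -- branch operations ------------------------------------------------
    def _apply_indels(self, chars: list[str], t: float) -> list[str]:
        eng = self.engine
        protected = self._protected()
        n_bases = sum(1 for c in chars if c != GAP)
        # deletions
        for _ in range(eng.indel_sites(n_bases, t)):
            length = eng.indel_length()
            pos = _ungapped_positions(chars)
            if len(pos) <= length + 10:
                continue
            start = int(self.rng.integers(0, len(pos) - length))
            cols = pos[start : start + length]
            if any(c in protected for c in cols):
                continue
            for c in cols:
                chars[c] = GAP
        # insertions
        for _ in range(eng.indel_sites(n_bases, t)):
            length = eng.indel_length()
            at = int(self.rng.integers(0, len(chars) + 1))
            if at in protected or (at - 1) in protected:
                continue
            ins = list(
                self.rng.choice(list(_BASES), size=length, p=self.cfg.spacer_freqs)
            )
            self._insert_columns(at, {self._current: ins})
        return chars

    def _break_rung(self, chars: list[str], layout: HairpinLayout, rung: int) -> None:
        """Turn the C-G rung ``rung`` steps from the loop into a T-G wobble.

        A single pyrimidine transition (C->T) on the 5' side: the wobble
        still pairs, so the stem stays folded until a later event fixes it.
        """
        left_col = layout.left[1] - 1 - rung
        chars[left_col] = "T"

    def _break_pair_hard(self, chars: list[str], col: int) -> None:
        """Substitute so the position can no longer pair with its partner."""
        cur = chars[col]
        chars[col] = "A" if cur in "CG" else "C"

    def _apply_plan_intermediate(
        self, chars: list[str], plan: _PlantPlan, stage: int
    ) -> None:
        layout = self.layouts[plan.hairpin]
        if plan.kind in ("one_cm", "multiple_cm"):
            for rung in plan.rungs:
                self._break_rung(chars, layout, rung)
        elif plan.kind == "within_stem_half":
            # two broken rungs inside s2 (the inner copy of the left half),
            # spread over two branches so each stays below the QC window
            # mismatch tolerance
            a, b = layout.left
            half = (b - a) // 2
            if stage == 2:
                self._break_pair_hard(chars, a + half + 1)
                # decoy mutation in the right half: the palindromic stem
                # would otherwise offer the opposite half as an equivalent
                # perfect reverse-complement source for the within-half copy
                self._break_pair_hard(chars, layout.right[0] + 1)
            else:
                self._break_pair_hard(chars, a + half + 3)

    def _apply_event(
        self, chars: list[str], parent_chars: list[str], plan: _PlantPlan
    ) -> None:
        layout = self.layouts[plan.hairpin]
        cfg = self.cfg

        def seg(cols: tuple[int, int]) -> str:
            return "".join(
                parent_chars[c] for c in range(*cols) if parent_chars[c] != GAP
            )

        def write(cols: tuple[int, int], content: str) -> None:
            targets = [c for c in range(*cols) if parent_chars[c] != GAP]
            assert len(targets) == len(content)
            for c, ch in zip(targets, content):
                chars[c] = ch

        def pos(col: int) -> int:
            return _col_to_pos(parent_chars, col)

        if plan.kind == "loop_inversion":
            k = 2
            cols = (layout.loop[0] - k, layout.loop[1] + k)
            write(cols, reverse_complement(seg(cols)))
            p1, p4 = pos(cols[0]), pos(cols[1])
            p3, p2 = p1, p4
        elif plan.kind in ("one_cm", "multiple_cm"):
            write(layout.right, reverse_complement(seg(layout.left)))
            p1, p4 = pos(layout.right[0]), pos(layout.right[1])
            p3, p2 = pos(layout.left[0]), pos(layout.left[1])
        elif plan.kind == "within_stem_half":
            a, b = layout.left
            half = (b - a) // 2
            s1_cols, s2_cols = (a, a + half), (a + half, b)
            write(s2_cols, reverse_complement(seg(s1_cols)))
            p1, p4 = pos(s2_cols[0]), pos(s2_cols[1])
            p3, p2 = pos(s1_cols[0]), pos(s1_cols[1])
        elif plan.kind == "insertion_in_stem":
            src_cols = (layout.left[1] - 6, layout.left[1])
            loop_len = layout.loop[1] - layout.loop[0]
            # k rungs below the loop; >= 1 so the interval widens, and the
            # source-target distance (loop + k) stays within the max of 8
            k = max(1, min(2, 8 - loop_len))
            at = layout.right[0] + k
            content = list(reverse_complement(seg(src_cols)))
            p1 = p4 = pos(at)
            p3, p2 = pos(src_cols[0]), pos(src_cols[1])
            self._insert_columns(at, {self._current: content})
            # shift() has widened the right interval; mark the new columns
            layout.inserted.update(range(at, at + len(content)))
        elif plan.kind == "instant_cm":
            # transition on both rung members: one Watson-Crick pair flips
            # to another on a single branch (C-G <-> T-A, G-C <-> A-T)
            flip = {"C": ("T", "A"), "T": ("C", "G"),
                    "G": ("A", "T"), "A": ("G", "C")}
            lcol = layout.left[0]
            rcol = layout.right[1] - 1
            chars[lcol], chars[rcol] = flip[chars[lcol]]
            self.instant_cms.append((plan.parent, plan.child, plan.hairpin))
            return
        else:  # pragma: no cover - guarded by PLANT_KINDS
            raise ValueError(f"unknown planting kind {plan.kind!r}")
        self.truth.append(
            TruthRecord(
                parent=plan.parent,
                child=plan.child,
                kind=_INTENDED_CATEGORY[plan.kind],
                p1=p1,
                p2=p2,
                p3=p3,
                p4=p4,
                hairpin=plan.hairpin,
            )
        )

    # -- main recursion ---------------------------------------------------
    def run(
        self,
        tree: dendropy.Tree,
        root_seq: str,
        layouts: list[HairpinLayout],
        plans: list[_PlantPlan],
    ) -> dict[str, str]:
        cfg = self.cfg
        self.layouts = layouts
        self.cats = list(
            self.rng.integers(0, cfg.gamma_categories, size=len(root_seq))
        )
        root_label = node_label(tree.seed_node)
        self.sequences = {root_label: list(root_seq)}
        self._current = root_label
        by_intermediate: dict[str, list[tuple[_PlantPlan, int]]] = {}
        by_branch: dict[tuple[str, str], list[_PlantPlan]] = {}
        for plan in plans:
            if plan.intermediate:
                by_intermediate.setdefault(plan.intermediate, []).append((plan, 1))
            if plan.intermediate2:
                by_intermediate.setdefault(plan.intermediate2, []).append((plan, 2))
            by_branch.setdefault((plan.parent, plan.child), []).append(plan)
        # planted hairpins are substitution-shielded along the lineage from
        # the root down to the event branch, so the planted mutations are
        # the only changes inside them on that path; other subtrees evolve
        # freely
        protect: dict[str, set[int]] = {}
        if plans:
            nodes_by_label = {
                node_label(n): n for n in tree.preorder_node_iter()
            }
            for plan in plans:
                node = nodes_by_label[plan.child]
                while node is not None and node is not tree.seed_node:
                    protect.setdefault(node_label(node), set()).add(plan.hairpin)
                    node = node.parent_node

        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent_label = node_label(node.parent_node)
            label = node_label(node)
            self._current = label
            t = (
                node.edge.length
                if node.edge.length is not None
                else cfg.branch_length_mean
            )
            chars = self.engine.substitute(
                self.sequences[parent_label], self.cats, t
            )
            self.sequences[label] = chars
            self._apply_indels(chars, t)
            parent_chars = self.sequences[parent_label]
            for h in sorted(protect.get(label, ())):
                a, b = self.layouts[h].span
                for c in range(a, b):
                    chars[c] = parent_chars[c]
            for plan in by_branch.get((parent_label, label), []):
                self._apply_event(chars, parent_chars, plan)
            for plan, stage in by_intermediate.get(label, []):
                self._apply_plan_intermediate(chars, plan, stage)
        return {label: "".join(seq) for label, seq in self.sequences.items()}


_INTENDED_CATEGORY = {
    "loop_inversion": "loop_inversion_only",
    "one_cm": "one_cm",
    "multiple_cm": "multiple_cm",
    "within_stem_half": "within_stem_half",
    "insertion_in_stem": "insertion_in_stem",
}


def annotate_structures(
    alignment: dict[str, str], layouts: list[HairpinLayout]
) -> dict[str, str]:
    """Per-node dot-bracket structures derived from the hairpin layout.

    Each stem rung is paired in a node's structure iff the node's bases at
    the rung columns still form an allowed pair (Watson-Crick or G-T);
    planted-insertion columns are unpaired (bulges).  This is the synthetic
    stand-in for structures predicted externally per node.
    """
    from .seqcore import ALLOWED_PAIRS

    structures: dict[str, str] = {}
    for label, gapped in alignment.items():
        pos_of = {}
        p = 0
        for col, c in enumerate(gapped):
            if c != GAP:
                pos_of[col] = p
                p += 1
        db = ["."] * p
        for lay in layouts:
            lcols = [
                c
                for c in range(*lay.left)
                if c in pos_of and c not in lay.inserted
            ]
            rcols = [
                c
                for c in range(*lay.right)
                if c in pos_of and c not in lay.inserted
            ]
            for k in range(min(len(lcols), len(rcols))):
                lc, rc = lcols[-1 - k], rcols[k]
                pair = gapped[lc] + gapped[rc]
                if pair in ALLOWED_PAIRS:
                    db[pos_of[lc]] = "("
                    db[pos_of[rc]] = ")"
        structures[label] = "".join(db)
    return structures


def generate_cluster(cfg: SimConfig) -> ClusterFixture:
    """Generate one cluster fixture: tree, aligned sequences, truth table."""
    rng = np.random.default_rng(cfg.seed)
    tree = generate_tree(cfg, rng)
    root_seq, _, layouts = generate_root(cfg, rng)
    plans = _plan_events(cfg, tree, layouts, rng)
    sim = _Simulator(cfg, rng)
    alignment = sim.run(tree, root_seq, layouts, plans)
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return ClusterFixture(
        tree=tree,
        newick=newick,
        alignment=alignment,
        truth=sim.truth,
        hairpins=sim.layouts,
        config=cfg,
        structures=annotate_structures(alignment, sim.layouts),
        instant_truth=sim.instant_cms,
    )


def null_evolve(
    tree: dendropy.Tree,
    root_seq: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    layouts: Optional[list[HairpinLayout]] = None,
) -> dict[str, str]:
    """Evolve a root sequence down a tree with no planting (null model)."""
    if any(
        (n.edge.length or 0) < 0 for n in tree.preorder_node_iter() if n.edge
    ):
        raise ValueError("negative branch length")
    sim = _Simulator(cfg, rng)
    return sim.run(tree, root_seq, layouts or [], [])


def _leaf_layouts(
    fixture: ClusterFixture, leaf: str
) -> list[HairpinLayout]:
    """Hairpin layouts mapped into a leaf's ungapped coordinate system."""
    gapped = fixture.alignment[leaf]
    pos_of = {}
    p = 0
    for col, c in enumerate(gapped):
        if c != GAP:
            pos_of[col] = p
            p += 1

    def mv(iv):
        inside = [pos_of[c] for c in range(*iv) if c in pos_of]
        return (inside[0], inside[-1] + 1) if inside else (0, 0)

    out = []
    for lay in fixture.hairpins:
        out.append(
            HairpinLayout(
                left=mv(lay.left),
                loop=mv(lay.loop),
                right=mv(lay.right),
                palindromic=lay.palindromic,
                inserted={pos_of[c] for c in lay.inserted if c in pos_of},
            )
        )
    return out


def null_replicates(
    fixture: ClusterFixture, n_replicates: int, seed: int
) -> list[ClusterFixture]:
    """Null replicates of a cluster, each rooted on a random terminal sequence.

    Replicates reuse the cluster's tree and evolution model, carry no
    planted events, and are returned as fixtures with their own
    layout-derived structure annotation (same treatment as the empirical
    side of the enrichment comparison).
    """
    out = []
    for r in range(n_replicates):
        rng = np.random.default_rng((seed % (2**31), fixture.config.seed, r))
        leaf = str(rng.choice(fixture.leaf_labels()))
        root_seq = fixture.alignment[leaf].replace(GAP, "")
        layouts = _leaf_layouts(fixture, leaf)
        sim = _Simulator(fixture.config, rng)
        alignment = sim.run(fixture.tree, root_seq, layouts, [])
        out.append(
            ClusterFixture(
                tree=fixture.tree,
                newick=fixture.newick,
                alignment=alignment,
                truth=[],
                hairpins=sim.layouts,
                config=fixture.config,
                structures=annotate_structures(alignment, sim.layouts),
            )
        )
    return out


# ---------------------------------------------------------------------------
# serialization


def write_fixture(fixture: ClusterFixture, outdir) -> None:
    """Serialise a fixture: alignment FASTA, newick, truth TSV, config JSON."""
    from pathlib import Path

    from .structure import write_structures

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(fixture.alignment, out / "alignment.fasta")
    (out / "tree.nwk").write_text(fixture.newick + "\n")
    if fixture.structures:
        write_structures(
            {
                label: (fixture.alignment[label].replace(GAP, ""), db)
                for label, db in fixture.structures.items()
            },
            out / "structures.txt",
        )
    with open(out / "truth.tsv", "w") as fh:
        fh.write("parent\tchild\tkind\tp1\tp2\tp3\tp4\thairpin\n")
        for t in fixture.truth:
            fh.write(
                f"{t.parent}\t{t.child}\t{t.kind}\t{t.p1}\t{t.p2}\t{t.p3}\t{t.p4}\t{t.hairpin}\n"
            )
    cfg = asdict(fixture.config)
    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=list) + "\n")
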