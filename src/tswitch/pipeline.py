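"""End-to-end orchestration: detection, QC, classification, statistics.

``analyze_cluster`` runs the per-cluster stages on an ancestor-annotated
alignment + tree; ``run_study`` adds the null replicates and the
empirical-versus-simulated enrichment comparison; ``write_report``
serialises the TSV report bundle.  All output coordinates are 0-based
half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .ancestry import (
    AnnotatedNode,
    branch_level,
    fitch_reconstruct,
    iter_parent_child,
    node_label,
)
from .classify import (
    CATEGORIES,
    CMRecord,
    PatternRecord,
    classify_pattern,
    detect_instantaneous_cms,
    substitution_spectrum,
    INSTANTANEOUS,
    TWO_STEP,
)
from .motifs import LoopRecord, extract_loops, loop_frequency_table
from .qc import (
    correction_factor,
    effective_length,
    high_quality_mask,
    inheritance_check,
    interval_in_mask,
)
from .seqcore import GAP, interval_columns
from .stats import EnrichmentResult, enrichment_test
from .structure import extract_hairpins, fold_max_pairing, parse_dotbracket
from .synthetic_data import ClusterFixture, null_replicates
from .tsm_engine import TSMEvent, dedup_overlapping, find_tsm, overlap_groups


@dataclass
class PipelineConfig:
    """Thresholds and run parameters for the full analysis."""

    min_copied: int = 6
    max_dist: int = 8
    min_explained: int = 1
    max_copied: int = 60
    qc_window: int = 10
    qc_base_child: int = 9
    qc_struct_child: int = 6
    qc_base_parent: int = 9
    min_loop: int = 3
    #: maximum pairing span of the built-in folder (local folding); None
    #: folds globally
    fold_max_span: Optional[int] = 100
    replicates: int = 5
    alpha: float = 0.05
    seed: int = 0
    reconstruct_ancestors: bool = False


@dataclass
class ClusterResult:
    """All per-cluster outputs of the detection/classification stages."""

    cluster_id: str
    patterns: list[PatternRecord] = field(default_factory=list)
    dropped: list[PatternRecord] = field(default_factory=list)
    instant_cms: list[tuple[str, CMRecord]] = field(default_factory=list)
    two_step_cms: list[CMRecord] = field(default_factory=list)
    loops: list[LoopRecord] = field(default_factory=list)
    effective_len: int = 0
    levels: dict[str, int] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def category_counts(self, branch_type: Optional[str] = None) -> dict[str, int]:
        counts = {cat: 0 for cat in CATEGORIES}
        for rec in self.patterns:
            if branch_type is None or rec.branch_type == branch_type:
                counts[rec.category] += 1
        return counts


def _pairwise_from_msa(a: str, b: str) -> tuple[str, str]:
    """Project two rows of one MSA onto their pairwise alignment."""
    cols = [(x, y) for x, y in zip(a, b) if not (x == GAP and y == GAP)]
    return "".join(x for x, _ in cols), "".join(y for _, y in cols)


def _annotate(
    alignment: dict[str, str],
    tree,
    config: PipelineConfig,
    structures: Optional[dict[str, str]] = None,
) -> dict[str, AnnotatedNode]:
    levels = branch_level(tree)
    leaves = {node_label(n) for n in tree.leaf_node_iter()}
    missing = [
        node_label(n)
        for n in tree.preorder_node_iter()
        if node_label(n) not in alignment
    ]
    if missing:
        internal_missing = [m for m in missing if m not in leaves]
        if internal_missing and config.reconstruct_ancestors:
            leaf_aln = {k: v for k, v in alignment.items() if k in leaves}
            alignment = {**alignment, **fitch_reconstruct(tree, leaf_aln)}
        else:
            raise ValueError(
                f"nodes without sequences: {missing[:5]} "
                "(enable reconstruct_ancestors for leaf-only input)"
            )
    annotations: dict[str, AnnotatedNode] = {}
    for label, gapped in alignment.items():
        seq = gapped.replace(GAP, "")
        if structures and label in structures:
            db = structures[label]
        else:
            db = fold_max_pairing(
                seq, min_loop=config.min_loop, max_span=config.fold_max_span
            )
        annotations[label] = AnnotatedNode(
            label=label,
            gapped_seq=gapped,
            structure=db,
            level=levels.get(label, -1),
            is_leaf=label in leaves,
        )
    return annotations


def _event_passes_qc(
    event: TSMEvent,
    parent: AnnotatedNode,
    child: AnnotatedNode,
    mask,
    grandchildren: list[AnnotatedNode],
    log: list[str],
) -> bool:
    src_cols = interval_columns(parent.gapped_seq, event.p3, event.p2)
    tgt_cols = interval_columns(parent.gapped_seq, event.p1, event.p4)
    if mask is not None and not (
        interval_in_mask(mask, src_cols) and interval_in_mask(mask, tgt_cols)
    ):
        log.append(f"{child.label}: event {event.target} outside high-quality region")
        return False
    # the source site must be identical between parent and child when it
    # does not overlap the target
    overlap = max(event.p3, event.p1) < min(event.p2, event.p4)
    if not overlap:
        if any(
            parent.gapped_seq[c] != child.gapped_seq[c] for c in src_cols
        ):
            log.append(f"{child.label}: event {event.target} source not identical")
            return False
    if not child.is_leaf:
        for cols in (src_cols, tgt_cols):
            if not inheritance_check(child, cols, grandchildren):
                log.append(f"{child.label}: event {event.target} not inherited")
                return False
    return True


def analyze_cluster(
    alignment: dict[str, str],
    tree,
    config: PipelineConfig,
    structures: Optional[dict[str, str]] = None,
    cluster_id: str = "cluster",
) -> ClusterResult:
    """Run detection, QC and classification on one annotated cluster."""
    result = ClusterResult(cluster_id=cluster_id)
    annotations = _annotate(alignment, tree, config, structures)
    result.levels = {a.label: a.level for a in annotations.values()}
    hairpins = {
        label: extract_hairpins(parse_dotbracket(a.structure), a.structure)
        for label, a in annotations.items()
    }
    children_of = {
        node_label(n): [node_label(c) for c in n.child_nodes()]
        for n in tree.preorder_node_iter()
    }
    root = node_label(tree.seed_node)

    masks = {}
    for node in tree.preorder_node_iter():
        label = node_label(node)
        if node is tree.seed_node or node.is_leaf():
            continue
        parent = annotations[node_label(node.parent_node)]
        kids = [annotations[c] for c in children_of[label]]
        masks[label] = high_quality_mask(
            annotations[label],
            parent,
            kids,
            window=config.qc_window,
            min_base_child=config.qc_base_child,
            min_struct_child=config.qc_struct_child,
            min_base_parent=config.qc_base_parent,
        )
    result.effective_len = effective_length(
        masks, {label: annotations[label].gapped_seq for label in masks}
    )
    result.masks = masks

    cm_loops = set()
    for parent_node, child_node in iter_parent_child(tree):
        v = annotations[node_label(parent_node)]
        w = annotations[node_label(child_node)]
        grandchildren = [annotations[g] for g in children_of.get(w.label, [])]
        pair_aln = _pairwise_from_msa(v.gapped_seq, w.gapped_seq)
        events = find_tsm(
            v.seq,
            w.seq,
            min_copied=config.min_copied,
            max_dist=config.max_dist,
            min_explained=config.min_explained,
            max_copied=config.max_copied,
            alignment=pair_aln,
        )
        mask = masks.get(v.label)
        events = [
            e
            for e in events
            if _event_passes_qc(e, v, w, mask, grandchildren, result.log)
        ]
        # one counted case per fully-overlapping group: the top-ranked
        # member that classifies; unclassifiable groups are logged
        for group in overlap_groups(events):
            record = None
            for event in group:
                record = classify_pattern(
                    event, v, w, hairpins[v.label], hairpins[w.label]
                )
                if record.category is not None:
                    break
            if record is None:
                continue
            if record.category is None:
                event = group[0]
                record = classify_pattern(
                    event, v, w, hairpins[v.label], hairpins[w.label]
                )
                result.log.append(
                    f"{w.label}: event {event.target} dropped: {record.drop_reason}"
                )
                result.dropped.append(record)
            else:
                result.patterns.append(record)
                result.two_step_cms.extend(record.cms)
        # instantaneous CMs on the same branch
        inst = detect_instantaneous_cms(
            v,
            w,
            hairpins[v.label],
            hairpins[w.label],
            mask=mask,
            grandchildren=grandchildren,
        )
        for rec in inst:
            result.instant_cms.append((w.label, rec))
            if w.is_leaf and rec.hairpin_loop is not None:
                cm_loops.add((v.label, rec.hairpin_loop))

    result.loops = extract_loops(tree, annotations, hairpins, masks, frozenset(cm_loops))
    # keep the root out of explicit pattern accounting: iter_parent_child
    # already guarantees nonroot parents
    result.log.append(f"{cluster_id}: root {root} excluded as reference")
    return result


# ---------------------------------------------------------------------------
# study-level orchestration


@dataclass
class StudyResult:
    """Empirical clusters, their null replicates, and the comparisons."""

    empirical: list[ClusterResult]
    replicates: list[list[ClusterResult]]  # [replicate][cluster]
    enrichment: list[EnrichmentResult] = field(default_factory=list)
    correction: list[float] = field(default_factory=list)

    def counts_matrix(
        self, results: list[ClusterResult], category: str, branch_type: str
    ) -> np.ndarray:
        return np.array(
            [r.category_counts(branch_type)[category] for r in results], dtype=float
        )


def run_study(
    fixtures: list[ClusterFixture],
    config: PipelineConfig,
    with_replicates: bool = True,
) -> StudyResult:
    """Analyze planted fixtures and (optionally) their null replicates."""
    empirical = [
        analyze_cluster(
            f.alignment,
            f.tree,
            config,
            structures=f.structures or None,
            cluster_id=f"cluster{i}",
        )
        for i, f in enumerate(fixtures)
    ]
    replicate_results: list[list[ClusterResult]] = []
    if with_replicates:
        per_fixture = [
            null_replicates(f, config.replicates, seed=config.seed) for f in fixtures
        ]
        for r in range(config.replicates):
            replicate_results.append(
                [
                    analyze_cluster(
                        per_fixture[i][r].alignment,
                        fixtures[i].tree,
                        config,
                        structures=per_fixture[i][r].structures or None,
                        cluster_id=f"cluster{i}_rep{r}",
                    )
                    for i in range(len(fixtures))
                ]
            )
    study = StudyResult(empirical=empirical, replicates=replicate_results)
    if replicate_results:
        emp_eff = sum(r.effective_len for r in empirical)
        for rep in replicate_results:
            sim_eff = sum(r.effective_len for r in rep)
            study.correction.append(
                correction_factor(emp_eff, sim_eff) if sim_eff > 0 else 1.0
            )
        if len(fixtures) >= 2:
            for branch_type in ("terminal", "internal"):
                for cat in CATEGORIES:
                    emp = study.counts_matrix(empirical, cat, branch_type)
                    sim = np.stack(
                        [
                            study.counts_matrix(rep, cat, branch_type)
                            for rep in replicate_results
                        ]
                    )
                    corr = np.asarray(study.correction)[:, None]
                    study.enrichment.append(
                        enrichment_test(
                            emp,
                            sim,
                            correction_factor=corr,
                            alpha=config.alpha,
                            category=cat,
                            branch_type=branch_type,
                        )
                    )
    return study


# ---------------------------------------------------------------------------
# report bundle


def _write_events_tsv(results: list[ClusterResult], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# coordinates 0-based half-open on the parent ungapped sequence\n"
            "cluster\tnode\tbranch_type\tcategory\tcm_count\t"
            "p1\tp2\tp3\tp4\tjump\tcopied_len\texplained\n"
        )
        for res in results:
            for rec in res.patterns:
                e = rec.event
                fh.write(
                    f"{res.cluster_id}\t{rec.node}\t{rec.branch_type}\t"
                    f"{rec.category}\t{rec.cm_count}\t{e.p1}\t{e.p2}\t{e.p3}\t"
                    f"{e.p4}\t{e.jump}\t{e.copied_len}\t{e.explained}\n"
                )


def _write_pattern_table(results: list[ClusterResult], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tall_branches\tterminal\tinternal\n")
        for cat in CATEGORIES:
            term = sum(r.category_counts("terminal")[cat] for r in results)
            intl = sum(r.category_counts("internal")[cat] for r in results)
            fh.write(f"{cat}\t{term + intl}\t{term}\t{intl}\n")


def _write_spectra(results: list[ClusterResult], outdir: Path) -> None:
    inst = [rec for r in results for _, rec in r.instant_cms]
    two = [rec for r in results for rec in r.two_step_cms]
    for name, records in (("instantaneous", inst), ("two_step", two)):
        spec = substitution_spectrum(records)
        spec.counts.to_csv(outdir / f"spectrum_{name}.tsv", sep="\t")
        with open(outdir / f"spectrum_{name}_summary.tsv", "w") as fh:
            fh.write("n\twobble_parent_share\twc_flip_share\n")
            fh.write(
                f"{spec.n}\t{spec.wobble_parent_share:.6f}\t{spec.wc_flip_share:.6f}\n"
            )


def _write_enrichment(study: StudyResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "category\tbranch_type\temp_mean\tsim_mean\tp_values\tenriched\tdepleted\n"
        )
        for res in study.enrichment:
            ps = ",".join(f"{p:.6g}" for p in res.p_values)
            fh.write(
                f"{res.category}\t{res.branch_type}\t{res.empirical.mean():.6f}\t"
                f"{res.simulated.mean():.6f}\t{ps}\t{res.enriched}\t{res.depleted}\n"
            )


def _write_level_counts(
    results: list[ClusterResult], trees: dict[str, object], path: Path
) -> None:
    from .ancestry import normalized_level_counts

    qualifying = {
        "one_cm",
        "cm_loop_inversion",
        "cm_parallel_loop",
        "multiple_cm",
        "loop_inversion_only",
        "insertion_in_stem",
    }
    records = [
        (r.cluster_id, rec.node)
        for r in results
        for rec in r.patterns
        if rec.category in qualifying
    ]
    rates = normalized_level_counts(records, trees) if records else {}
    with open(path, "w") as fh:
        fh.write("# root branch excluded from denominators\nlevel\trate\n")
        for lev, rate in sorted(rates.items()):
            fh.write(f"{lev}\t{rate:.6f}\n")


def write_report(
    study: StudyResult,
    trees: dict[str, object],
    config: PipelineConfig,
    outdir,
) -> None:
    """Write the TSV report bundle for a finished study."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_events_tsv(study.empirical, out / "events.tsv")
    _write_pattern_table(study.empirical, out / "patterns.tsv")
    _write_spectra(study.empirical, out)
    if study.enrichment:
        _write_enrichment(study, out / "enrichment.tsv")
    _write_level_counts(study.empirical, trees, out / "level_counts.tsv")
    from .qc import mask_intervals

    with open(out / "masks.bed", "w") as fh:
        fh.write("# high-quality regions; 0-based half-open alignment columns\n")
        for res in study.empirical:
            for label, mask in res.masks.items():
                for start, stop in mask_intervals(mask):
                    fh.write(f"{res.cluster_id}\t{label}\t{start}\t{stop}\n")
    loops = [l for r in study.empirical for l in r.loops]
    cm_loops = [l for l in loops if l.has_instantaneous_cm]
    if loops and cm_loops:
        table = loop_frequency_table(cm_loops, loops)
        table.to_csv(out / "loop_frequencies.tsv", sep="\t", index=False)
    with open(out / "log.txt", "w") as fh:
        for res in study.empirical:
            for line in res.log:
                fh.write(line + "\n")
    meta = asdict(config)
    meta["effective_length_empirical"] = sum(
        r.effective_len for r in study.empirical
    )
    meta["correction_factors"] = study.correction
    meta["notes"] = [
        "tree levels exclude the root branch",
        "category precedence: CM+loop categories > multiple_cm > one_cm",
    ]
    (out / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def detect_pair(
    parent_seq: str,
    child_seq: str,
    config: Optional[PipelineConfig] = None,
) -> list[TSMEvent]:
    """Detection on a bare parent/child pair (no tree, no QC)."""
    config = config or PipelineConfig()
    return dedup_overlapping(
        find_tsm(
            parent_seq,
            child_seq,
            min_copied=config.min_copied,
            max_dist=config.max_dist,
            min_explained=config.min_explained,
            max_copied=config.max_copied,
        )
    )
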