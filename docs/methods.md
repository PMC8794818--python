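# Methods

## The template-switch model

A template switch mutation (TSM) is parameterised by four switch points
p1–p4 on the parent (reference) sequence, all 0-based: replication copies
the parent up to p1, switches to the nearby source interval [p3, p2) which
it copies in reverse-complement orientation, and resumes at p4. The child
therefore equals `parent[:p1] + revcomp(parent[p3:p2]) + parent[p4:]`.
When p2 > p1 the jump is only producible by an interstrand-forward switch;
p2 ≤ p1 covers the sequence-indistinguishable intrastrand and
interstrand-backward cases and is reported as `leftward`.

Detection inverts the model. For one branch, the parent and child are
compared through their pairwise alignment (projected from the cluster
alignment, or computed with edlib for bare pairs; gap-in-parent runs
attach to the following parent residue so pure insertions occupy a
well-defined target). An event is admissible when the child segment
aligned to the target columns equals the reverse complement of a parent
source segment exactly, with

- copied length ≥ `min_copied` (default 6 nt) and ≤ `max_copied`
  (default 60 nt — events are local, hairpin-scale copies; the cap also
  bounds the enumeration),
- at most `max_dist` (default 8 nt) between source and target intervals,
  counted strictly between them and 0 when they touch or overlap (stem
  halves touch at the loop),
- at least `min_explained` (default 1) aligned parent/child differences
  removed by the event.

Admissible events are ranked by explained differences (descending), then
copied length (descending), then leftmost coordinates. Preferring the
*longer* copy at equal explanatory power keeps the full geometry of a
copy: nested sub-events of, say, a loop inversion would otherwise win the
ranking, and after fully-overlapping events are collapsed to one counted
case per site the surviving representative would no longer span both stem
halves, making the loop-inversion category unreachable. When the
top-ranked member of a fully-overlapping group matches no category, the
next-ranked member that does classify is counted instead (one case per
site either way); unclassifiable sites are logged with a drop reason.

## Quality control

High-quality regions are computed per internal node with a 10-column
sliding window: ≥ 9 base identities against the node's own parent, and a
single child jointly providing ≥ 9 base identities and ≥ 6 secondary
structure identities. IUPAC uncertainties with overlapping base sets are
unified before comparison; shared gap columns count as base identities
but never as structure identities; windows shorter than 10 columns at
alignment ends are skipped. A column is high quality if any covering
window passes. Event source and target must lie in high-quality columns,
the source must be identical between parent and child when it does not
overlap the target, and events on internal children must be inherited in
identical form by at least one grandchild. The effective length (total
internal-node bases inside high-quality columns) normalises simulated
counts via the correction factor `empirical_eff / simulated_eff`.

## Pattern classification

Each surviving event is assigned to the hairpin (of the parent's
structure) that its source and target overlap most. A compensatory
mutation is attributed per stem rung when (1) the event overlaps an
observed difference, (2) the corrected rung bridges source and target in
separate stem halves, (3) source and target are equally distant from the
loop, measured in rung indices from the closing pair so bulges are
ignored, and (4) an imperfect pair becomes perfect Watson–Crick. Rungs
whose pair is fully broken in the parent (hence absent from its predicted
structure) are completed from the child's homologous stem. Category
precedence is: CM+loop categories (inversion, then parallel loop changes)
over multiple CMs over one CM; then loop inversion only; then insertions
(net copy gain bridging different halves); then the asymmetric categories
(loop-to-stem and within-stem-half), which additionally require the child
to retain a hairpin with its loop at the same alignment columns. Category
minima follow the pattern table: ≥ 1 explained difference for one-CM and
insertion patterns, ≥ 2 for all others.

Instantaneous CMs are detected on the same branches: hairpins with loops
at identical alignment columns in parent and child, perfect Watson–Crick
stems on both sides, no ambiguity codes in the reference hairpin,
high-quality placement, and loop inheritance for internal children; each
differing rung yields one record. Base-pair substitution spectra report
the 16×16 parent→child pair counts plus two marginal shares: the fraction
of two-step records whose parent pair is a G–T/T–G wobble, and the
fraction of instantaneous records of type A–T↔G–C or C–G↔T–A (compatible
with a wobble intermediate).

## Secondary structure

The built-in folder maximises the number of nested base pairs over
Watson–Crick plus the G–T wobble with a minimum hairpin loop of 3 nt (the
shortest loop length tabulated), deterministic traceback (a base stays
unpaired whenever optimality allows, otherwise pairs its leftmost
admissible partner), and an optional maximum pairing span for local
folding of long sequences. Base-pair maximisation, not energy
minimisation, keeps the folder dependency-free and exactly checkable
against brute-force enumeration; it is, however, a poor predictor for
long evolved sequences, where near-optimal alternatives proliferate.
Externally predicted structures are therefore accepted everywhere as
dot-bracket input, and the synthetic studies use the generator's own
per-node structure annotation (see below) — the analog of running an
external folder, which is how the real analysis obtains its structures.

## Synthetic data

The generator emulates clusters of closely related structural RNA genes:
a root of configurable length (default 1000 nt) carrying hairpins
(default 3) with perfectly reverse-complementary stems of 5–12 bp and
loops of 3–8 nt biased toward the GNRA family, separated by unstructured
spacers; evolution down a random join tree (default 10 leaves, mean
branch length 0.02 substitutions/site) under GTR+gamma (default
transition/transversion exchangeabilities 2:1, shape 1, four discrete
categories) with Poisson indels (default rate 0.002/site split equally
between insertions and deletions, geometric length with mean 3, capped at
10).

The root alphabet is deliberately constrained so that the designed
hairpins are the *provably unique* optimum of the max-pairing fold:
pyrimidine ({C,T}) left stem halves (hence purine right halves), purine
loops whose positions beyond the third are adenine, and poly-A spacers.
With this layout no loop or spacer base can pair a stem base at equal
pairing count, so the fold is forced — which the tests verify directly.
The cost is reduced compositional realism (documented here rather than
hidden): stems are pyrimidine/purine-asymmetric, spacers are
homopolymeric, and loop variety is restricted to the purine alphabet.
Substitutions during evolution re-introduce all bases.

Planted events realise the pattern categories by construction:
loop-spanning self-copies (inversions), opposite-half copies after one or
two planted C→T wobbles on an ancestral branch (one/multiple CMs),
within-half copies restoring a planted-broken internal inverted repeat
(with the breaking mutations spread over two ancestor branches so each
stays below the QC window tolerance, and a decoy mutation in the opposite
half so the palindromic stem offers no equivalent cross-half source),
and left-half copies inserted into the right half (stem insertions).
Instantaneous CMs are planted as same-branch transitions on both members
of one rung (C–G↔T–A, G–C↔A–T). Planted hairpins are shielded from
random substitutions and indels along the lineage from the root to the
event branch, so the planted mutations are the only changes inside them
on that path; all other subtrees evolve freely. Spacers stay at least
12 nt wide so one hairpin can never serve as its neighbour's copy source
within the 8-nt distance cap. Every fixture carries a truth table and
per-node dot-bracket annotation (each designed rung paired iff the
node's bases still form an allowed pair; planted-insertion columns are
bulges).

Null replicates (default five, matching the enrichment design) re-evolve
each cluster's tree from a randomly selected terminal sequence with the
same model and no planting, and receive the same layout-derived structure
annotation, so both sides of the enrichment comparison are treated
identically.

What passing synthetic tests do *not* show: performance under realistic
base composition, alignment and ancestral-reconstruction error (the
fixtures carry true alignments and true ancestors), structure-prediction
error, or recombination among gene copies. They do show that detection,
QC, classification and the enrichment statistics are internally correct
and calibrated under the stated model.

## Statistics

Loop motif/length comparisons use the two-sided one-proportion z test
with the background frequency as the null proportion. The
empirical-versus-simulated comparison computes per-cluster counts per
category and branch type, multiplies simulated counts by the correction
factor, and applies Welch's unequal-variance t test against each
replicate; a category is enriched only when significant (p < 0.05 by
default) against *every* replicate with the empirical mean above each
replicate mean, and depleted symmetrically. Welch's form is used because
the variance-equality of the two sides is not guaranteed; no
multiple-testing correction is applied across categories, mirroring the
single-table design. Requiring significance against all five replicates
makes the procedure conservative, which the permutation-calibration test
confirms.

## Problem sizes and numerical choices

Test and acceptance runs use 50 planted clusters of 1000 nt / 10 leaves
for end-to-end recovery, 100 two-cluster null studies and 20 six-cluster
planted studies for calibration, exhaustive folding checks over all
sequences of length ≤ 10 plus 200 random sequences of length ≤ 14, and
500-case oracle/round-trip checks at lengths ≤ 40/60. The Nussinov fill
runs as a numba kernel; the traceback tie-break, event-ranking order and
Fitch root tie-break (state order A < C < G < T < gap) are fixed for
bit-reproducibility, and identical configuration plus seed reproduces
report bundles byte for byte. Tree levels assign terminals 0 and internal
nodes one above their minimum child level; the root, which has no branch,
is excluded from level-rate denominators. The root node is never used as
a comparison reference.

## Known limitations

- The folder ignores thermodynamics, pseudoknots and suboptimal
  ensembles; dot-bracket input is the fidelity path.
- Under alignment ambiguity (repeats, palindromes) the switch points of
  an event are not unique; the ranking picks a deterministic
  representative, and boundary coordinates may differ from the generating
  event even when the reconstruction is exact.
- The category taxonomy resolves overlapping definitions by fixed
  precedence; events matching no category are dropped explicitly and
  logged rather than forced.
- Degenerate IUPAC input is accepted everywhere (uncertainty unification,
  no-pair folding); strict removal of degenerate sequences is left to
  preprocessing policy.
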