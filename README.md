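# tswitch

Template-switch mutation analysis for RNA gene sequence histories.

RNA hairpins require perfect pairing between the two halves of their stem,
and how such reverse-complement structure arises and is maintained is a
long-standing puzzle: random point mutations are unlikely to create long
perfect stems, and compensatory mutations (CMs) — a change on one side of a
stem matched by the restoring change on the other — seem to appear faster
than independent substitutions allow. Template switch mutations (TSMs)
offer a mechanistic answer: during DNA replication the polymerase briefly
copies a nearby template in reverse-complement orientation before returning
to the original strand. A single TSM can create a perfect stem, fix one or
several mismatched stem pairs at once, or invert a hairpin loop in place.

`tswitch` detects and classifies these footprints in ancestral sequence
histories. Given a gapped alignment with ancestor-annotated internal nodes
and the corresponding rooted tree (PAGAN2-style output; a Fitch parsimony
stand-in is built in for leaf-only input), it:

- detects **four-switch-point TSM events** between every nonroot parent and
  its child: the target interval [p1, p4) of the parent is replaced in the
  child by the exact reverse complement of the source interval [p3, p2),
  with a minimum copied length of 6 nt and a maximum source–target distance
  of 8 nt;
- applies sliding-window **quality control** (10-column windows with 9/10
  base identity against the parent, 9/10 base identity plus 6/10 secondary
  structure identity against at least one child, identical-form inheritance
  for internal children);
- **classifies** each event by its impact on hairpin structure: one CM,
  multiple CMs, CM with loop inversion or parallel loop changes, loop
  inversion only, asymmetric copies within a stem half or from loop to
  stem, and stem insertions;
- detects **instantaneous CMs** (initial and restoring change on the same
  branch, both stems perfectly Watson–Crick paired);
- compares hairpin-loop **motif and length frequencies** (GNRA/TNCG/CTTG
  families, loop lengths 3–8) between CM-carrying hairpins and the
  background, with two-sided one-proportion z tests;
- tests category **enrichment** against five simulated null replicates of
  each cluster (counts corrected by relative effective length; Welch t
  test against every replicate).

A first-class synthetic-data module generates hairpin-bearing clusters that
evolve by GTR+gamma substitutions and indels down a random tree, with
planted TSM events and a truth table, plus the matching null simulator —
so the whole pipeline can be exercised and calibrated end to end.

## Worked example

Simulate three clusters, run the full analysis against five null
replicates, and write the report bundle:

```
$ tswitch all --clusters 3 --seed 7 --length 600 --outdir demo
fixtures and report under demo
```

`demo/report/patterns.tsv` tabulates classified events by category and
branch type (terminal = child is a leaf):

```
category	all_branches	terminal	internal
one_cm	2	2	0
multiple_cm	3	2	1
loop_inversion_only	1	1	0
within_stem_half	2	2	0
...
```

`demo/report/events.tsv` lists each event's switch points (0-based
half-open, parent coordinates), jump direction, copied length and the
number of parent/child differences it explains:

```
cluster	node	branch_type	category	cm_count	p1	p2	p3	p4	jump	copied_len	explained
cluster0	N5	internal	multiple_cm	2	244	240	229	255	leftward	11	2
cluster0	L0	terminal	one_cm	1	46	42	30	58	leftward	12	1
```

The `multiple_cm` row says: on the branch into node N5, replacing parent
positions [244, 255) with the reverse complement of [229, 240) — a
leftward (intrastrand or interstrand-backward) switch copying the opposite
stem half — converts two mismatched stem pairs into perfect Watson–Crick
pairs at once and removes both observed parent/child differences.

The bundle also contains the instantaneous/two-step base-pair substitution
spectra, loop-frequency tables, per-level normalized event rates,
high-quality-region masks (`masks.bed`), the enrichment table with
per-replicate p-values, and a log with the reason for every dropped event.

Single stages (`simulate`, `detect`, `classify`, `stats`) run on each
other's serialized outputs; `detect` also accepts a bare two-record
parent/child FASTA.

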