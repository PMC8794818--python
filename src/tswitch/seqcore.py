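"""DNA alphabet handling and pre-analysis sequence filtering.

Sequences are DNA strings over the unambiguous alphabet ``ACGT`` plus the
IUPAC ambiguity codes and the gap symbol ``-``.  RNA input is mapped to the
DNA alphabet on ingest (U -> T); all coordinates in the package are 0-based
half-open on the ungapped sequence unless stated otherwise.
"""

from __future__ import annotations

from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: IUPAC code -> set of unambiguous bases it stands for.
IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}

#: Complement table on IUPAC codes (ambiguity classes map onto each other).
COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_COMP_TRANS = str.maketrans(COMPLEMENT)

#: Watson-Crick base pairs and the G-T (G-U) wobble, as 2-character strings.
WC_PAIRS = frozenset({"AT", "TA", "GC", "CG"})
WOBBLE_PAIRS = frozenset({"GT", "TG"})
ALLOWED_PAIRS = WC_PAIRS | WOBBLE_PAIRS


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside the IUPAC DNA set."""


def sanitize(seq: str) -> str:
    """Normalise raw input: uppercase, U -> T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    validate(s, allow_gap=True)
    return s


def validate(seq: str, allow_gap: bool = False) -> None:
    ok = set(IUPAC_SETS)
    if allow_gap:
        ok.add(GAP)
    bad = set(seq) - ok
    if bad:
        raise InvalidSequenceError(f"invalid characters: {sorted(bad)!r}")


def ungap(seq: str) -> str:
    return seq.replace(GAP, "")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet.

    The input must be ungapped; ambiguity codes are complemented to the code
    of the complementary base set (R<->Y, K<->M, B<->V, D<->H; S, W, N are
    self-complementary classes).
    """
    if GAP in seq:
        raise InvalidSequenceError("reverse_complement expects an ungapped sequence")
    validate(seq)
    return seq.translate(_COMP_TRANS)[::-1]


def iupac_intersect(a: str, b: str) -> Optional[str]:
    """Intersect two IUPAC codes; return the code of the common base set.

    Returns ``None`` when the base sets are disjoint.
    """
    try:
        sa, sb = IUPAC_SETS[a], IUPAC_SETS[b]
    except KeyError as exc:
        raise InvalidSequenceError(f"invalid IUPAC code: {exc.args[0]!r}") from exc
    common = sa & sb
    return _SET_TO_CODE[common] if common else None


def unify_uncertainties(a: str, b: str) -> tuple[str, str]:
    """Unify homologous uncertainties of two aligned sequences column-wise.

    At every column where the two base sets overlap, both sequences receive
    the intersection code; columns with disjoint sets (true differences) and
    gap columns are left unchanged.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    out_a, out_b = list(a), list(b)
    for i, (x, y) in enumerate(zip(a, b)):
        if x == GAP or y == GAP or x == y:
            continue
        common = iupac_intersect(x, y)
        if common is not None:
            out_a[i] = common
            out_b[i] = common
    return "".join(out_a), "".join(out_b)


def _max_window_mismatches(a: str, b: str, window: int) -> int:
    """Largest mismatch count of any sliding window over the pairwise overlap."""
    n = min(len(a), len(b))
    if n == 0:
        return 0
    mism = [1 if a[i] != b[i] else 0 for i in range(n)]
    w = min(window, n)
    cur = sum(mism[:w])
    best = cur
    for i in range(w, n):
        cur += mism[i] - mism[i - w]
        if cur > best:
            best = cur
    return best


def redundancy_filter(
    seqs: Iterable[str], window: int = 20, min_mismatches: int = 2
) -> list[str]:
    """Discard near-duplicate sequences by the sliding-window mismatch rule.

    A sequence is kept iff, against every earlier *kept* sequence, some window
    of ``window`` columns contains at least ``min_mismatches`` mismatches.
    Comparison is column-wise on the given (equal-length or aligned) strings;
    a gap opposite a base counts as a mismatch. Order is preserved and the
    result is deterministic given the input order.
    """
    kept: list[str] = []
    for s in seqs:
        if all(
            _max_window_mismatches(s, k, window) >= min_mismatches for k in kept
        ):
            kept.append(s)
    return kept


def position_columns(gapped: str) -> list[int]:
    """Alignment column of each ungapped position."""
    return [i for i, c in enumerate(gapped) if c != GAP]


def interval_columns(gapped: str, lo: int, hi: int) -> range:
    """Alignment-column range covering ungapped interval [lo, hi)."""
    cols = position_columns(gapped)
    if not 0 <= lo <= hi <= len(cols):
        raise ValueError(f"interval [{lo},{hi}) out of range")
    start = cols[lo] if lo < len(cols) else len(gapped)
    stop = cols[hi] if hi < len(cols) else len(gapped)
    if lo == hi:
        stop = start
    return range(start, stop)


def read_fasta(path, do_sanitize: bool = True) -> dict[str, str]:
    """Read a (possibly gapped) multi-record FASTA into an ordered dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        out[rec.id] = sanitize(s) if do_sanitize else s.upper()
    return out


def write_fasta(records: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")
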