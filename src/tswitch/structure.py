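"""Secondary-structure prediction stand-in and hairpin anatomy.

The built-in folder maximises the number of nested base pairs over the
canonical Watson-Crick pairs plus the G-T (G-U) wobble, with a minimum
hairpin-loop length.  It is deterministic (fixed traceback preference) and
is meant as a structure *stand-in*: externally predicted structures (e.g.
minimum-free-energy folds) can be supplied as dot-bracket strings anywhere a
structure is consumed.

Positions are 0-based on the ungapped sequence; intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .seqcore import GAP, IUPAC_SETS, WC_PAIRS, validate

# base encoding for the DP kernel: A=0 C=1 G=2 T=3, ambiguity codes = 4
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# allowed pair lookup: AT TA GC CG GT TG
_PAIRABLE = np.zeros((5, 5), dtype=np.bool_)
for _x, _y in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIRABLE[_x, _y] = True


class StructureFormatError(ValueError):
    """Raised for malformed dot-bracket input."""


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


@njit(cache=True)
def _nussinov(codes, pairable, min_loop, max_span):  # pragma: no cover - jitted
    n = codes.shape[0]
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # interval [i, j)
            best = dp[i + 1, j]
            kmax = j - 1
            if kmax - i > max_span:
                kmax = i + max_span
            for k in range(i + min_loop + 1, kmax + 1):
                if pairable[codes[i], codes[k]]:
                    cand = 1 + dp[i + 1, k] + dp[k + 1, j]
                    if cand > best:
                        best = cand
            dp[i, j] = best
    # traceback: leave the 5' base unpaired whenever optimality allows
    # (only forced pairs form), otherwise pair it with the leftmost
    # admissible partner; deterministic
    partner = np.full(n, -1, dtype=np.int32)
    stack_i = np.empty(2 * n + 2, dtype=np.int32)
    stack_j = np.empty(2 * n + 2, dtype=np.int32)
    top = 0
    stack_i[0] = 0
    stack_j[0] = n
    while top >= 0:
        i = stack_i[top]
        j = stack_j[top]
        top -= 1
        if j - i < min_loop + 2:
            continue
        target = dp[i, j]
        if target == 0:
            continue
        if dp[i + 1, j] == target:
            top += 1
            stack_i[top] = i + 1
            stack_j[top] = j
            continue
        kmax = j - 1
        if kmax - i > max_span:
            kmax = i + max_span
        for k in range(i + min_loop + 1, kmax + 1):
            if pairable[codes[i], codes[k]]:
                if 1 + dp[i + 1, k] + dp[k + 1, j] == target:
                    partner[i] = k
                    partner[k] = i
                    top += 1
                    stack_i[top] = i + 1
                    stack_j[top] = k
                    top += 1
                    stack_i[top] = k + 1
                    stack_j[top] = j
                    break
    return partner


def fold_max_pairing(seq: str, min_loop: int = 3, max_span: int | None = None) -> str:
    """Fold an ungapped sequence by nested base-pair maximisation.

    Pairs are drawn from {A-T, T-A, G-C, C-G, G-T, T-G}; ambiguity codes
    never pair.  ``max_span`` optionally restricts the distance between
    paired positions (local folding, as in sliding-window folders); ``None``
    means unrestricted.  Returns a dot-bracket string.
    """
    if GAP in seq:
        raise ValueError("fold_max_pairing expects an ungapped sequence")
    validate(seq)
    n = len(seq)
    if n == 0:
        return ""
    span = n if max_span is None else int(max_span)
    partner = _nussinov(_encode(seq), _PAIRABLE, int(min_loop), span)
    out = []
    for i in range(n):
        j = partner[i]
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


def parse_dotbracket(db: str) -> dict[int, int]:
    """Stack-match a dot-bracket string into a symmetric pair table."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureFormatError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif c != ".":
            raise StructureFormatError(f"invalid structure character {c!r}")
    if stack:
        raise StructureFormatError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def render_dotbracket(pairs: dict[int, int], n: int) -> str:
    out = ["."] * n
    for i, j in pairs.items():
        if i < j:
            out[i] = "("
            out[j] = ")"
    return "".join(out)


@dataclass(frozen=True)
class HairpinElement:
    """One hairpin: stem halves, loop, closing pair and stem-interior bulges.

    ``rungs`` lists the stem base pairs from the closing pair outward, so
    rung index measures distance from the loop ignoring bulges.
    """

    left_half: tuple[int, int]
    right_half: tuple[int, int]
    loop: tuple[int, int]
    closing_pair: tuple[int, int]
    bulges: frozenset[int] = field(default_factory=frozenset)
    rungs: tuple[tuple[int, int], ...] = ()

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_half[0], self.right_half[1])

    def loop_len(self) -> int:
        return self.loop[1] - self.loop[0]


def extract_hairpins(pairs: dict[int, int], db: str) -> list[HairpinElement]:
    """Extract one element per innermost helix-closed loop.

    Starting from each closing pair, the stem is extended outward through
    consecutive pairs; unpaired positions passed over inside the stem are
    recorded as bulges.  Extension stops at a multiloop or exterior junction
    (i.e. when the next enclosing candidate pairs elsewhere).
    """
    n = len(db)
    partner = [pairs.get(i, -1) for i in range(n)]
    hairpins: list[HairpinElement] = []
    for i, j in sorted((i, j) for i, j in pairs.items() if i < j):
        if any(partner[k] >= 0 for k in range(i + 1, j)):
            continue  # not an innermost pair
        loop = (i + 1, j)
        rungs = [(i, j)]
        bulges: set[int] = set()
        lo, hi = i, j
        while True:
            a = lo - 1
            left_skip: list[int] = []
            while a >= 0 and partner[a] < 0:
                left_skip.append(a)
                a -= 1
            if a < 0 or partner[a] < hi:
                break  # exterior, or a closes a different helix (multiloop)
            b = partner[a]
            between_right = list(range(hi + 1, b))
            if any(partner[k] >= 0 for k in between_right):
                break  # another helix intervenes: multiloop junction
            bulges.update(left_skip)
            bulges.update(between_right)
            rungs.append((a, b))
            lo, hi = a, b
        hairpins.append(
            HairpinElement(
                left_half=(lo, i + 1),
                right_half=(j, hi + 1),
                loop=loop,
                closing_pair=(i, j),
                bulges=frozenset(bulges),
                rungs=tuple(rungs),
            )
        )
    return hairpins


def gapped_structure(db: str, gapped_seq: str) -> str:
    """Project an ungapped dot-bracket string onto alignment columns."""
    if len(db) != len(gapped_seq) - gapped_seq.count(GAP):
        raise ValueError("structure length does not match ungapped sequence length")
    it = iter(db)
    return "".join(GAP if c == GAP else next(it) for c in gapped_seq)


def structure_identity(
    db_a: str, gapped_a: str, db_b: str, gapped_b: str
) -> np.ndarray:
    """Per-alignment-column structure identity; gap columns are never identities."""
    if len(gapped_a) != len(gapped_b):
        raise ValueError("gapped sequences must have equal length")
    ga = gapped_structure(db_a, gapped_a)
    gb = gapped_structure(db_b, gapped_b)
    return np.fromiter(
        (x == y and x != GAP for x, y in zip(ga, gb)),
        dtype=np.bool_,
        count=len(ga),
    )


def is_perfect_stem(h: HairpinElement, seq: str) -> bool:
    """True iff every stem rung is a Watson-Crick pair and there are no bulges."""
    if h.bulges:
        return False
    return all(seq[i] + seq[j] in WC_PAIRS for i, j in h.rungs)


def stem_is_wc(h: HairpinElement, seq: str) -> bool:
    """Watson-Crick check on the rungs only (bulges tolerated)."""
    return all(seq[i] + seq[j] in WC_PAIRS for i, j in h.rungs)


def has_ambiguity(seq: str, start: int, end: int) -> bool:
    return any(len(IUPAC_SETS.get(c, frozenset())) != 1 for c in seq[start:end])


def read_structures(path) -> dict[str, tuple[str, str]]:
    """Read Vienna-style records: '>id' line, sequence line, structure line."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureFormatError(f"expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise StructureFormatError("truncated structure record")
        name = lines[i][1:].split()[0]
        out[name] = (lines[i + 1], lines[i + 2])
        i += 3
    return out


def write_structures(records: dict[str, tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, (seq, db) in records.items():
            fh.write(f">{name}\n{seq}\n{db}\n")
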