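"""Reading, validating and writing RNA secondary structures and CHS annotations.

Structures are exchanged as bpseq (three whitespace-separated columns:
1-based position, base, pairing partner or 0) or as plain dot-bracket with
round brackets.  Coaxial helical stacking (CHS) annotations are plain text,
one junction per line::

    J1 H1H3
    J2 H1H4 H2H3
    J3 none

Helix indices in an ``HxHy`` token refer to the helices meeting at the
junction, numbered 1..n in 5'->3' order with index 1 the parent (exterior)
helix.  All coordinates exposed by this module are 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property

__all__ = [
    "SecondaryStructure",
    "CHSAnnotation",
    "StructureError",
    "BpseqError",
    "NonContiguousIndexError",
    "InvalidBaseError",
    "PartnerRangeError",
    "ReciprocityError",
    "DotBracketError",
    "AnnotationError",
    "parse_bpseq",
    "write_bpseq",
    "parse_dotbracket",
    "write_dotbracket",
    "parse_annotation",
    "write_annotation",
    "remove_crossing_pairs",
]

VALID_BASES = frozenset("ACGU")


class StructureError(ValueError):
    """Base class for structure/annotation format problems."""


class BpseqError(StructureError):
    pass


class NonContiguousIndexError(BpseqError):
    pass


class InvalidBaseError(BpseqError):
    pass


class PartnerRangeError(BpseqError):
    pass


class ReciprocityError(BpseqError):
    pass


class DotBracketError(StructureError):
    pass


class AnnotationError(StructureError):
    pass


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA sequence with a set of base pairs.

    ``pairs`` holds 1-based ``(i, j)`` tuples with ``i < j``.  Each position
    participates in at most one pair.  Crossing pairs (pseudoknots) are
    representable so that :func:`remove_crossing_pairs` can clean them, but
    every downstream stage requires a non-crossing structure.
    """

    sequence: str
    pairs: frozenset = frozenset()
    name: str = ""

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise InvalidBaseError(f"invalid bases in sequence: {sorted(bad)}")
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        n = len(seq)
        seen = set()
        for i, j in pairs:
            if not (1 <= i < j <= n):
                raise PartnerRangeError(f"pair ({i}, {j}) out of range for length {n}")
            for p in (i, j):
                if p in seen:
                    raise StructureError(f"position {p} participates in more than one pair")
                seen.add(p)

    def __len__(self) -> int:
        return len(self.sequence)

    @cached_property
    def partner(self) -> dict:
        """Map position -> pairing partner (both directions)."""
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    @cached_property
    def sorted_pairs(self) -> tuple:
        return tuple(sorted(self.pairs))

    def is_noncrossing(self) -> bool:
        ps = self.sorted_pairs
        for a in range(len(ps)):
            i, j = ps[a]
            for k, l in ps[a + 1:]:
                if k >= j:
                    break
                if i < k < j < l:
                    return False
        return True

    def base(self, i: int) -> str:
        return self.sequence[i - 1]


@dataclass(frozen=True)
class CHSAnnotation:
    """Coaxial helical stacking pattern of one junction.

    ``stacked_pairs`` is a set of unordered helix-index pairs ``{x, y}``;
    empty means CHS status "none".  Each helix index may appear in at most
    one stacked pair, and a helix cannot stack on itself.
    """

    junction_id: str
    stacked_pairs: frozenset = frozenset()

    def __post_init__(self):
        canon = frozenset(frozenset(int(h) for h in p) for p in self.stacked_pairs)
        object.__setattr__(self, "stacked_pairs", canon)
        seen = set()
        for p in canon:
            if len(p) != 2:
                raise AnnotationError(
                    f"{self.junction_id}: a helix cannot stack on itself ({set(p)})")
            if seen & p:
                raise AnnotationError(
                    f"{self.junction_id}: helix index {sorted(seen & p)} "
                    "appears in more than one stacked pair")
            seen |= p

    @property
    def is_none(self) -> bool:
        return not self.stacked_pairs


# ---------------------------------------------------------------------------
# bpseq

def parse_bpseq(text: str, name: str = "") -> SecondaryStructure:
    """Parse bpseq content into a :class:`SecondaryStructure`.

    Raises a distinct :class:`BpseqError` subclass naming the offending line
    for: non-contiguous indices, invalid bases, partners out of range and
    non-reciprocal pairing.
    """
    bases = []
    partners = []
    lineno_of = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or not line[0].isdigit():
            continue  # tolerate comment/header lines
        fields = line.split()
        if len(fields) != 3:
            raise BpseqError(f"line {lineno}: expected 3 columns, got {len(fields)}")
        try:
            idx = int(fields[0])
            partner = int(fields[2])
        except ValueError:
            raise BpseqError(f"line {lineno}: non-integer index or partner") from None
        if idx != len(bases) + 1:
            raise NonContiguousIndexError(
                f"line {lineno}: index {idx}, expected {len(bases) + 1}")
        b = fields[1].upper().replace("T", "U")
        if b not in VALID_BASES:
            raise InvalidBaseError(f"line {lineno}: invalid base {fields[1]!r}")
        bases.append(b)
        partners.append(partner)
        lineno_of.append(lineno)
    n = len(bases)
    if n == 0:
        raise BpseqError("no bpseq records found")
    pairs = set()
    for pos0, partner in enumerate(partners):
        i = pos0 + 1
        if partner == 0:
            continue
        if not (1 <= partner <= n) or partner == i:
            raise PartnerRangeError(
                f"line {lineno_of[pos0]}: partner {partner} out of range")
        if partners[partner - 1] != i:
            raise ReciprocityError(
                f"line {lineno_of[pos0]}: position {i} names partner {partner} "
                f"but position {partner} names {partners[partner - 1]}")
        pairs.add((min(i, partner), max(i, partner)))
    return SecondaryStructure("".join(bases), frozenset(pairs), name=name)


def write_bpseq(s: SecondaryStructure) -> str:
    lines = []
    if s.name:
        lines.append(f"# {s.name}")
    partner = s.partner
    for i, b in enumerate(s.sequence, start=1):
        lines.append(f"{i} {b} {partner.get(i, 0)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# dot-bracket (convenience reader; round, pseudoknot-free brackets only)

def parse_dotbracket(text: str, name: str = "") -> SecondaryStructure:
    """Parse ``[>name\\n]sequence\\nstructure`` dot-bracket content."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        name = name or lines[0][1:].strip()
        lines = lines[1:]
    if len(lines) != 2:
        raise DotBracketError("expected a sequence line and a structure line")
    seq, db = lines
    if len(seq) != len(db):
        raise DotBracketError("sequence and structure lengths differ")
    pairs = set()
    stack = []
    for pos, c in enumerate(db, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise DotBracketError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif c != ".":
            raise DotBracketError(f"unsupported character {c!r} at position {pos}")
    if stack:
        raise DotBracketError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(seq, frozenset(pairs), name=name)


def write_dotbracket(s: SecondaryStructure) -> str:
    if not s.is_noncrossing():
        raise DotBracketError("cannot write a crossing structure as dot-bracket")
    db = ["."] * len(s)
    for i, j in s.pairs:
        db[i - 1] = "("
        db[j - 1] = ")"
    head = f">{s.name}\n" if s.name else ""
    return f"{head}{s.sequence}\n{''.join(db)}\n"


# ---------------------------------------------------------------------------
# pseudoknot fallback cleaner

def remove_crossing_pairs(s: SecondaryStructure) -> SecondaryStructure:
    """Return a maximum-cardinality non-crossing subset of ``s.pairs``.

    Interval dynamic program over the existing pairs (each position pairs at
    most once, so the transition is O(1)).  Ties in cardinality are broken by
    preferring the lexicographically smallest sorted pair list, which the DP
    achieves by preferring to keep the pair at the leftmost position.
    """
    if s.is_noncrossing():
        return s
    partner = {i: j for i, j in s.pairs}
    memo = {}

    def best(i: int, j: int):
        # best (count, sorted pair tuple) using pairs with both ends in [i, j]
        if i >= j:
            return (0, ())
        key = (i, j)
        hit = memo.get(key)
        if hit is not None:
            return hit
        res = best(i + 1, j)
        k = partner.get(i)
        if k is not None and i < k <= j:
            c1, p1 = best(i + 1, k - 1)
            c2, p2 = best(k + 1, j)
            take = (c1 + c2 + 1, ((i, k),) + p1 + p2)
            # prefer larger count; on ties the taken list starts at i and is
            # lexicographically smaller than any list starting beyond i
            if take[0] >= res[0]:
                res = take
        memo[key] = res
        return res

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * len(s) + 100))
    try:
        _, kept = best(1, len(s))
    finally:
        sys.setrecursionlimit(old)
    return SecondaryStructure(s.sequence, frozenset(kept), name=s.name)


# ---------------------------------------------------------------------------
# CHS annotations

_CHS_TOKEN = re.compile(r"^H(\d+)H(\d+)$")


def parse_annotation(text: str) -> list:
    """Parse CHS annotation content into a list of :class:`CHSAnnotation`."""
    records = []
    seen_ids = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        junction_id, pattern_tokens = tokens[0], tokens[1:]
        if junction_id in seen_ids:
            raise AnnotationError(f"line {lineno}: duplicate junction id {junction_id!r}")
        seen_ids.add(junction_id)
        if not pattern_tokens:
            raise AnnotationError(f"line {lineno}: missing pattern (use 'none')")
        if [t.lower() for t in pattern_tokens] == ["none"]:
            records.append(CHSAnnotation(junction_id))
            continue
        stacked = set()
        for tok in pattern_tokens:
            m = _CHS_TOKEN.match(tok)
            if not m:
                raise AnnotationError(f"line {lineno}: unrecognized token {tok!r}")
            x, y = int(m.group(1)), int(m.group(2))
            if x == y:
                raise AnnotationError(f"line {lineno}: self-stack {tok!r}")
            stacked.add(frozenset((x, y)))
        try:
            records.append(CHSAnnotation(junction_id, frozenset(stacked)))
        except AnnotationError as e:
            raise AnnotationError(f"line {lineno}: {e}") from None
    return records


def write_annotation(annotations) -> str:
    lines = []
    for a in annotations:
        if a.is_none:
            lines.append(f"{a.junction_id} none")
        else:
            toks = sorted((min(p), max(p)) for p in a.stacked_pairs)
            lines.append(a.junction_id + " " + " ".join(f"H{x}H{y}" for x, y in toks))
    return "\n".join(lines) + "\n"
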