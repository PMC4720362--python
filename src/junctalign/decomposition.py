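"""Decompose a pseudoknot-free secondary structure into typed elements.

A *helix* is a maximal run of nested base pairs in which consecutive pairs
are separated only by unpaired bases (internal loops and bulges are part of
the helix).  The enclosed loop at a helix's inner end is either a *hairpin*
(no enclosed pairs) or an *n-way junction* (n >= 3 bordering pairs: the
closing pair of the enclosing helix plus the outer pairs of n-1 child
helices).  Loops bordered by exactly two pairs are internal loops/bulges and
are absorbed into the helix; they are never elements of their own.

Membership convention: junction and hairpin elements contain only unpaired
bases; the bordering base pairs belong to the adjacent helices, so element
contents are disjoint.  Bases exterior to all pairs (5' of the first pair,
3' of the last, and between domains) belong to no element and are excluded
from alignment scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structure_io import SecondaryStructure

__all__ = ["Element", "ElementSet", "decompose", "junction_loop_regions"]

HELIX = "helix"
JUNCTION = "junction"
HAIRPIN = "hairpin"


@dataclass(frozen=True)
class Element:
    """One structural element: a helix, an n-way junction, or a hairpin loop.

    ``closing_pairs``: for a helix, all of its base pairs in outer->inner
    order; for a junction, the n bordering pairs with the exterior (parent)
    pair first and the child pairs following in 5'->3' order; for a hairpin,
    its single closing pair.

    ``nucleotides``: sorted 1-based positions belonging to the element
    (helix: paired bases plus internal-loop/bulge bases; loops: unpaired
    bases only).

    ``loop_regions``: for junctions, the n single-stranded ranges
    ``(start, end)`` in 5'->3' order; a range with ``start > end`` is empty.
    """

    kind: str
    closing_pairs: tuple
    nucleotides: tuple
    degree: int | None = None
    loop_regions: tuple = ()

    def __post_init__(self):
        if self.kind == JUNCTION:
            if self.degree is None or self.degree < 3:
                raise ValueError("a junction must have degree >= 3")
            if len(self.closing_pairs) != self.degree:
                raise ValueError("a junction needs exactly `degree` bordering pairs")
        elif self.kind == HAIRPIN and len(self.closing_pairs) != 1:
            raise ValueError("a hairpin has exactly one closing pair")

    @property
    def start(self) -> int:
        """5'-most position of the element's outermost bordering pair."""
        return self.closing_pairs[0][0]


@dataclass(frozen=True)
class ElementSet:
    """The elements of one structure plus their nesting relations.

    ``children[k]`` lists the indices (into ``elements``) of the elements
    directly enclosed by element k: a helix encloses its single loop element,
    a junction encloses its child helices in 5'->3' order.  ``roots`` are the
    outermost helices in 5'->3' order.
    """

    structure: SecondaryStructure
    elements: tuple
    children: dict
    roots: tuple

    @property
    def helices(self) -> list:
        return [e for e in self.elements if e.kind == HELIX]

    @property
    def junctions(self) -> list:
        return [e for e in self.elements if e.kind == JUNCTION]

    @property
    def hairpins(self) -> list:
        return [e for e in self.elements if e.kind == HAIRPIN]

    def junction_ids(self) -> dict:
        """Map junction element -> id "J1", "J2", ... in 5'->3' order."""
        js = sorted(self.junctions, key=lambda e: e.start)
        return {e: f"J{k}" for k, e in enumerate(js, start=1)}

    def to_tsv(self) -> str:
        rows = ["kind\tdegree\tpositions"]
        for e in self.elements:
            deg = e.degree if e.degree is not None else ""
            rows.append(f"{e.kind}\t{deg}\t{','.join(map(str, e.nucleotides))}")
        return "\n".join(rows) + "\n"


def _nesting_forest(pairs):
    """Return (children_of, roots) of the pair nesting forest."""
    ordered = sorted(pairs)
    children_of = {p: [] for p in ordered}
    roots = []
    stack = []
    for p in ordered:
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        if stack:
            children_of[stack[-1]].append(p)
        else:
            roots.append(p)
        stack.append(p)
    return children_of, roots


def decompose(s: SecondaryStructure) -> ElementSet:
    """Decompose ``s`` into helix, junction and hairpin elements."""
    if not s.pairs:
        raise ValueError("structure must contain at least one base pair")
    if not s.is_noncrossing():
        raise ValueError("structure contains crossing pairs; clean it first "
                         "(remove_crossing_pairs)")
    children_of, pair_roots = _nesting_forest(s.pairs)

    elements = []
    children = {}

    def build_helix(outer_pair) -> int:
        # collect the helix chain: follow unique children
        chain = [outer_pair]
        while len(children_of[chain[-1]]) == 1:
            chain.append(children_of[chain[-1]][0])
        positions = []
        for (i, j), (i2, j2) in zip(chain, chain[1:]):
            positions.extend((i, j))
            positions.extend(range(i + 1, i2))       # 5' internal-loop bases
            positions.extend(range(j2 + 1, j))       # 3' internal-loop bases
        positions.extend(chain[-1])
        helix = Element(HELIX, tuple(chain), tuple(sorted(positions)))
        idx = len(elements)
        elements.append(helix)
        children[idx] = []

        inner = chain[-1]
        kids = children_of[inner]
        if not kids:  # hairpin loop
            a, b = inner
            loop = tuple(range(a + 1, b))
            hp = Element(HAIRPIN, (inner,), loop)
            children[idx].append(len(elements))
            elements.append(hp)
            children[len(elements) - 1] = []
        else:  # n-way junction, n = len(kids) + 1 >= 3
            borders = [inner] + kids
            n = len(borders)
            regions = []
            loop_positions = []
            for k in range(n):
                left = borders[k][0] if k == 0 else borders[k][1]
                right = borders[k + 1][0] if k + 1 < n else borders[0][1]
                regions.append((left + 1, right - 1))
                loop_positions.extend(range(left + 1, right))
            junc = Element(JUNCTION, tuple(borders), tuple(loop_positions),
                           degree=n, loop_regions=tuple(regions))
            jidx = len(elements)
            elements.append(junc)
            children[idx].append(jidx)
            children[jidx] = [build_helix(kid) for kid in kids]
        return idx

    root_indices = tuple(build_helix(p) for p in pair_roots)
    return ElementSet(s, tuple(elements), children, root_indices)


def junction_loop_regions(e: Element) -> list:
    """The n single-stranded ranges of a junction, 5'->3'; may be empty."""
    if e.kind != JUNCTION:
        raise ValueError("junction_loop_regions expects a junction element")
    return list(e.loop_regions)
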