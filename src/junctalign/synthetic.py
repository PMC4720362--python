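"""Seeded generator of pseudoknot-free structures with CHS-labelled junctions.

A :class:`TopologySpec` describes a structure tree: helix stem lengths with
internal loops/bulges, junction degrees with per-junction CHS patterns and
loop-region lengths, and hairpin loop lengths.  :func:`generate_structure`
realizes a spec as a concrete sequence plus base-pair set whose
decomposition recovers the spec exactly; paired positions draw uniformly
from the six canonical/wobble pair types (GC, CG, AU, UA, GU, UG), unpaired
positions uniformly from ACGU.  One seeded pseudo-random stream per call:
identical seeds give byte-identical output.

:func:`perturb` adds sequence-level noise (loop-base substitutions and
small loop indels) without ever changing the topology or the CHS labels.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .structure_io import SecondaryStructure, CHSAnnotation
from .decomposition import decompose, HELIX, JUNCTION, HAIRPIN

__all__ = ["HairpinSpec", "JunctionSpec", "HelixSpec", "TopologySpec",
           "generate_structure", "generate_pair", "perturb", "random_topology"]

PAIR_TYPES = ("GC", "CG", "AU", "UA", "GU", "UG")
LOOP_BASES = "ACGU"


@dataclass(frozen=True)
class HairpinSpec:
    loop: int = 4

    def __post_init__(self):
        if self.loop < 1:
            raise ValueError("hairpin loop length must be >= 1 (>= 3 recommended)")

    def length(self) -> int:
        return self.loop


@dataclass(frozen=True)
class JunctionSpec:
    """An n-way junction: n-1 branch helices, n loop-region lengths, a CHS pattern."""

    branches: tuple
    loops: tuple
    chs: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "branches", tuple(self.branches))
        object.__setattr__(self, "loops", tuple(int(x) for x in self.loops))
        object.__setattr__(
            self, "chs", frozenset(frozenset(int(h) for h in p) for p in self.chs))
        if len(self.branches) < 2:
            raise ValueError("a junction must have degree >= 3 "
                             "(at least two branch helices)")
        if len(self.loops) != self.degree:
            raise ValueError(f"{self.degree}-way junction needs {self.degree} "
                             "loop-region lengths")
        if any(x < 0 for x in self.loops):
            raise ValueError("loop-region lengths must be >= 0")
        seen = set()
        for p in self.chs:
            if len(p) != 2 or max(p) > self.degree or min(p) < 1:
                raise ValueError(f"invalid CHS pair {set(p)} for a "
                                 f"{self.degree}-way junction")
            if seen & p:
                raise ValueError("a helix index may appear in only one stacked pair")
            seen |= p

    @property
    def degree(self) -> int:
        return len(self.branches) + 1

    def length(self) -> int:
        return sum(self.loops) + sum(b.length() for b in self.branches)


@dataclass(frozen=True)
class HelixSpec:
    """Stem lengths (pairs) separated by internal loops ((5'len, 3'len) each)."""

    stems: tuple
    child: object  # JunctionSpec | HairpinSpec
    internal_loops: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "stems", tuple(int(x) for x in self.stems))
        object.__setattr__(self, "internal_loops",
                           tuple((int(a), int(b)) for a, b in self.internal_loops))
        if not self.stems or any(x < 1 for x in self.stems):
            raise ValueError("each stem must contain >= 1 pair")
        if len(self.internal_loops) != len(self.stems) - 1:
            raise ValueError("need exactly one internal loop between consecutive stems")
        if any(a + b < 1 or a < 0 or b < 0 for a, b in self.internal_loops):
            raise ValueError("an internal loop/bulge must contain >= 1 base")

    def length(self) -> int:
        return (2 * sum(self.stems)
                + sum(a + b for a, b in self.internal_loops)
                + self.child.length())


@dataclass(frozen=True)
class TopologySpec:
    root: HelixSpec
    seed: int = 0
    name: str = ""


def generate_structure(spec: TopologySpec):
    """Realize a spec as ``(SecondaryStructure, [CHSAnnotation])``."""
    rng = random.Random(spec.seed)
    n = spec.root.length()
    bases = [None] * (n + 1)  # 1-based
    pairs = []
    annotations = []
    jcounter = [0]

    def place_pair(i, j):
        p = rng.choice(PAIR_TYPES)
        bases[i], bases[j] = p[0], p[1]
        pairs.append((i, j))

    def place_loop(lo, hi):  # inclusive, may be empty
        for p in range(lo, hi + 1):
            bases[p] = rng.choice(LOOP_BASES)

    def place_helix(h: HelixSpec, lo, hi):
        l, r = lo, hi
        for k, stem in enumerate(h.stems):
            for _ in range(stem):
                place_pair(l, r)
                l, r = l + 1, r - 1
            if k < len(h.internal_loops):
                a, b = h.internal_loops[k]
                place_loop(l, l + a - 1)
                place_loop(r - b + 1, r)
                l, r = l + a, r - b
        place_child(h.child, l, r)

    def place_child(c, lo, hi):
        if isinstance(c, HairpinSpec):
            assert hi - lo + 1 == c.loop
            place_loop(lo, hi)
        else:
            jcounter[0] += 1
            annotations.append(CHSAnnotation(f"J{jcounter[0]}", c.chs))
            cursor = lo
            for k, branch in enumerate(c.branches):
                place_loop(cursor, cursor + c.loops[k] - 1)
                cursor += c.loops[k]
                place_helix(branch, cursor, cursor + branch.length() - 1)
                cursor += branch.length()
            place_loop(cursor, cursor + c.loops[-1] - 1)
            assert cursor + c.loops[-1] - 1 == hi

    place_helix(spec.root, 1, n)
    name = spec.name or f"synthetic(seed={spec.seed})"
    s = SecondaryStructure("".join(bases[1:]), frozenset(pairs), name=name)
    return s, annotations


def generate_pair(spec: TopologySpec, seed1: int, seed2: int):
    """Two same-topology structures with independently sampled sequences."""
    s1, a1 = generate_structure(replace(spec, seed=seed1))
    s2, a2 = generate_structure(replace(spec, seed=seed2))
    return (s1, a1), (s2, a2)


# ---------------------------------------------------------------------------
# perturbation (topology- and CHS-preserving)

def _loop_runs(s: SecondaryStructure):
    """Contiguous single-stranded runs inside elements, as (anchor, positions).

    ``anchor`` is the position the run follows (used for insertions into
    empty junction regions).  Hairpin loops, junction loop regions and
    internal-loop strands each form one run.
    """
    d = decompose(s)
    runs = []
    for e in d.elements:
        if e.kind == HAIRPIN:
            runs.append((e.closing_pairs[0][0], list(e.nucleotides), HAIRPIN))
        elif e.kind == JUNCTION:
            for a, b in e.loop_regions:
                runs.append((a - 1, list(range(a, b + 1)), JUNCTION))
        else:
            chain = e.closing_pairs
            for (i, j), (i2, j2) in zip(chain, chain[1:]):
                if i2 > i + 1:
                    runs.append((i, list(range(i + 1, i2)), HELIX))
                if j > j2 + 1:
                    runs.append((j2, list(range(j2 + 1, j)), HELIX))
    runs.sort(key=lambda r: r[0])
    return runs


def perturb(s: SecondaryStructure, annotations,
            substitution_rate: float = 0.0, indel_rate: float = 0.0,
            seed: int = 0):
    """Sequence-level noise with the topology and CHS labels preserved.

    ``substitution_rate``: per-base probability of replacing a loop base by
    a different one.  ``indel_rate``: per-loop-run probability of one
    single-base insertion or deletion (deletions never touch paired bases
    and never empty a hairpin loop; insertions into empty junction regions
    are allowed since they cannot change the branch count).
    """
    rng = random.Random(seed)
    bases = list(s.sequence)
    runs = _loop_runs(s)
    for _, positions, _ in runs:
        for p in positions:
            if rng.random() < substitution_rate:
                bases[p - 1] = rng.choice([b for b in LOOP_BASES if b != bases[p - 1]])
    deleted = set()
    inserted = {}  # insert after old position -> list of bases
    for anchor, positions, kind in runs:
        if rng.random() >= indel_rate:
            continue
        do_insert = rng.random() < 0.5
        if not do_insert and (not positions or (kind == HAIRPIN and len(positions) <= 1)):
            do_insert = True
        if do_insert:
            if not positions and kind == HELIX:
                continue  # never widen a bulge that the spec did not declare
            after = rng.choice([anchor] + positions) if positions else anchor
            inserted.setdefault(after, []).append(rng.choice(LOOP_BASES))
        else:
            deleted.add(rng.choice(positions))

    new_bases = []
    index_map = {}
    for b in inserted.get(0, ()):  # anchor 0: before position 1
        new_bases.append(b)
    for old in range(1, len(bases) + 1):
        if old not in deleted:
            new_bases.append(bases[old - 1])
            index_map[old] = len(new_bases)
        for b in inserted.get(old, ()):
            new_bases.append(b)
    new_pairs = frozenset((index_map[i], index_map[j]) for i, j in s.pairs)
    out = SecondaryStructure("".join(new_bases), new_pairs,
                             name=f"{s.name}|perturbed(seed={seed})" if s.name else "")
    return out, list(annotations)


# ---------------------------------------------------------------------------
# random specs for property tests and fixtures

def _random_chs(rng: random.Random, degree: int, allow_none: bool = True) -> frozenset:
    choices = ["none"] if allow_none else []
    choices += ["one", "one"]
    if degree >= 4:
        choices.append("two")
    kind = rng.choice(choices)
    if kind == "none":
        return frozenset()
    idx = list(range(1, degree + 1))
    rng.shuffle(idx)
    pairs = [frozenset(idx[0:2])]
    if kind == "two":
        pairs.append(frozenset(idx[2:4]))
    return frozenset(pairs)


def _random_helix(rng: random.Random, child) -> HelixSpec:
    nstems = rng.choice((1, 1, 2))
    stems = tuple(rng.randint(2, 5) for _ in range(nstems))
    iloops = []
    for _ in range(nstems - 1):
        a, b = rng.randint(0, 2), rng.randint(0, 2)
        if a + b == 0:
            a = 1
        iloops.append((a, b))
    return HelixSpec(stems, child, tuple(iloops))


def random_topology(seed: int, degrees=(3, 4, 5), max_depth: int = 1,
                    allow_none: bool = True, name: str = "") -> TopologySpec:
    """A random junction-bearing spec; the root helix always closes a junction."""
    rng = random.Random(seed)

    def branch(depth: int) -> HelixSpec:
        if depth < max_depth and rng.random() < 0.25:
            return _random_helix(rng, junction(depth + 1))
        return _random_helix(rng, HairpinSpec(rng.randint(3, 6)))

    def junction(depth: int) -> JunctionSpec:
        degree = rng.choice(degrees)
        branches = tuple(branch(depth) for _ in range(degree - 1))
        loops = tuple(rng.randint(1, 4) for _ in range(degree))
        return JunctionSpec(branches, loops, _random_chs(rng, degree, allow_none))

    return TopologySpec(_random_helix(rng, junction(0)), seed=seed, name=name)
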