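"""Shared fixtures and independent oracles.

The oracles re-derive expected values by explicit enumeration and direct
summation, never through the recurrences they check: maximum non-crossing
pair subsets by subset enumeration, element alignment scores by enumerating
every global alignment, and tree alignment scores by enumerating every
constrained order-preserving node mapping and summing gamma over its lines.
"""

from __future__ import annotations

import itertools
from math import inf

import pytest

from junctalign import element_scoring as es
from junctalign.decomposition import HELIX, JUNCTION, HAIRPIN
from junctalign.element_scoring import ScoringParams
from junctalign.structure_io import parse_dotbracket


@pytest.fixture(scope="session")
def params() -> ScoringParams:
    return ScoringParams.default()


@pytest.fixture
def ss():
    """Build a structure from (sequence, dot-bracket) strings."""

    def make(seq: str, db: str, name: str = "test"):
        return parse_dotbracket(f"{seq}\n{db}\n", name=name)

    return make


# ---------------------------------------------------------------------------
# oracle: maximum non-crossing subset by brute force (<= ~12 pairs)

def brute_force_max_noncrossing(pairs):
    pairs = sorted(pairs)

    def noncrossing(subset):
        for (i, j), (k, l) in itertools.combinations(subset, 2):
            if i < k < j < l or k < i < l < j:
                return False
        return True

    best = ()
    for r in range(len(pairs), -1, -1):
        candidates = [c for c in itertools.combinations(pairs, r) if noncrossing(c)]
        if candidates:
            best = min(candidates)  # lexicographically smallest sorted pair list
            break
    return frozenset(best)


# ---------------------------------------------------------------------------
# oracle: global element alignment by enumerating every alignment

def brute_force_global_align(items1, items2, p: ScoringParams) -> float:
    g = p.gap_penalty

    def sub(a, b):
        pa, pb = isinstance(a, es.PairItem), isinstance(b, es.PairItem)
        if pa and pb:
            return p.pair_matrix[(a.bases, b.bases)]
        if not pa and not pb:
            return p.single_matrix[(a.base, b.base)]
        return -inf

    best = -inf

    def rec(i, j, acc):
        nonlocal best
        if i == len(items1) and j == len(items2):
            best = max(best, acc)
            return
        if i < len(items1) and j < len(items2):
            s = sub(items1[i], items2[j])
            if s > -inf:
                rec(i + 1, j + 1, acc + s)
        if i < len(items1):
            rec(i + 1, j, acc + items1[i].nt * g)
        if j < len(items2):
            rec(i, j + 1, acc + items2[j].nt * g)

    rec(0, 0, 0.0)
    return best


# ---------------------------------------------------------------------------
# oracle: constrained tree alignment by enumerating every node mapping

def _gamma_match(a, b, p):
    return (es.gamma_junction(a, b, p) if a.kind == JUNCTION
            else es.gamma_same_type(a, b, p))


def enumerate_alignment_scores(x, y, p: ScoringParams):
    """Scores of every constrained line-set for the subtree pair (x, y).

    A line-set matches same-kind nodes (junctions only with equal
    signatures, children strictly position-wise), preserves ancestry and
    sibling order, may gap a node and descend past it, and may stop at any
    subtree pair (the empty set, score 0).
    """
    yield 0.0
    kx, ky = x.kind, y.kind
    if kx == ky == JUNCTION:
        if x.signature == y.signature:
            g = es.gamma_junction(x, y, p)
            options = [list(enumerate_alignment_scores(cx, cy, p))
                       for cx, cy in zip(x.children, y.children)]
            for child_scores in itertools.product(*options):
                yield g + sum(child_scores)
    elif kx == ky == HELIX:
        g = es.gamma_same_type(x, y, p)
        for sub in enumerate_alignment_scores(x.children[0], y.children[0], p):
            yield g + sub  # sub == 0.0 covers matching the helices alone
    elif kx == ky == HAIRPIN:
        yield es.gamma_same_type(x, y, p)
    else:
        if kx == HELIX:
            for sub in enumerate_alignment_scores(x.children[0], y, p):
                yield es.gamma_gap(x, p) + sub
        elif kx == JUNCTION:
            for cx in x.children:
                for sub in enumerate_alignment_scores(cx, y, p):
                    yield es.gamma_gap(x, p) + sub
        if ky == HELIX:
            for sub in enumerate_alignment_scores(x, y.children[0], p):
                yield es.gamma_gap(y, p) + sub
        elif ky == JUNCTION:
            for cy in y.children:
                for sub in enumerate_alignment_scores(x, cy, p):
                    yield es.gamma_gap(y, p) + sub


def brute_force_tree_alignment(t1, t2, p: ScoringParams) -> float:
    """Best score over all subtree pairs and all constrained mappings."""
    best = 0.0
    for x in t1.nodes:
        for y in t2.nodes:
            best = max(best, max(enumerate_alignment_scores(x, y, p)))
    return best
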