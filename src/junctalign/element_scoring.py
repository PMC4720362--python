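"""Node-content scoring (gamma) under RIBOSUM85-60.

The score of aligning two same-type nodes is a global (end-to-end)
Needleman-Wunsch alignment of their contents with a linear gap penalty g
per nucleotide:

* hairpins: one alignment of the two loop sequences (4x4 single-base block);
* junctions: the sum, over loop regions k = 1..n, of the alignment of
  region k of one junction with region k of the other (signature equality
  guarantees equal region counts; regions are never cross-matched);
* helices: one alignment over the ordered mixed item lists (base pairs in
  outer->inner order with internal-loop/bulge bases interleaved), where
  pair items are scored by the 16x16 pair block, single bases by the 4x4
  block, and pair-vs-single matches are prohibited (equivalently scored as
  both-gapped); gapping a pair costs 2g.

Matching a node against the empty node aligns all of its nucleotides to
gaps: g times the nucleotide count (a base pair counts two).

Junction-junction gamma adds the CHS bonus: s + w when the signatures are
equal and both junctions carry a CHS motif, s + w/2 when the signatures are
equal and both are "none", and -inf otherwise.  -inf is the IEEE sentinel:
it annihilates sums and loses every max, which is exactly the required
algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

from .decomposition import Element, HELIX, JUNCTION, HAIRPIN
from .tree_model import TreeNode

__all__ = [
    "NEG_INF", "ScoringParams", "load_matrix_file",
    "node_items", "node_nt_count",
    "gamma_gap", "gamma_same_type", "gamma_junction",
    "global_align",
]

NEG_INF = float("-inf")

BASES = "ACGU"


def load_matrix_file(path_or_text) -> tuple:
    """Parse a matrix asset (SINGLE 4x4 block + PAIR 16x16 block).

    Blocks may be given as upper triangles; they are symmetrized.  Returns
    ``(single, pair)`` dicts keyed by ("A","C") / ("AU","GC") style tuples.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    elif "\n" in str(path_or_text):
        text = str(path_or_text)
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    blocks = {}
    section, header = None, None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        tok = line.split()
        if tok[0] in ("SINGLE", "PAIR"):
            section = tok[0]
            blocks[section] = {}
            header = None
            continue
        if section is None:
            raise ValueError("matrix file must start with a SINGLE or PAIR header")
        if header is None:
            header = tok
            continue
        label, values = tok[0], [float(v) for v in tok[1:]]
        # values fill columns right-aligned: full row or upper triangle
        cols = header[len(header) - len(values):]
        for c, v in zip(cols, values):
            blocks[section][(label, c)] = v
            blocks[section][(c, label)] = v
    single, pair = blocks.get("SINGLE", {}), blocks.get("PAIR", {})
    if len(single) != 16 or len(pair) != 256:
        raise ValueError(f"incomplete matrix: {len(single)}/16 single and "
                         f"{len(pair)}/256 pair entries")
    return single, pair


def _default_matrices():
    with resources.files("junctalign.data").joinpath("ribosum85_60.mat").open() as fh:
        return load_matrix_file(fh)


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrices plus gap penalty g (< 0) and junction weight w.

    Defaults: RIBOSUM85-60, g = -1, w = 100.
    """

    single_matrix: dict
    pair_matrix: dict
    gap_penalty: float = -1.0
    junction_weight: float = 100.0
    matrix_id: str = "RIBOSUM85-60"

    def __post_init__(self):
        if self.gap_penalty >= 0:
            raise ValueError("gap_penalty must be negative")
        if self.junction_weight < 0:
            raise ValueError("junction_weight must be >= 0")

    @classmethod
    def default(cls, gap_penalty: float = -1.0, junction_weight: float = 100.0):
        single, pair = _default_matrices()
        return cls(single, pair, gap_penalty, junction_weight)

    @classmethod
    def from_matrix_file(cls, path, gap_penalty: float = -1.0,
                         junction_weight: float = 100.0, matrix_id: str | None = None):
        single, pair = load_matrix_file(path)
        return cls(single, pair, gap_penalty, junction_weight,
                   matrix_id=matrix_id or str(path))

    def with_weight(self, w: float) -> "ScoringParams":
        return replace(self, junction_weight=w)


# ---------------------------------------------------------------------------
# node contents

@dataclass(frozen=True)
class PairItem:
    i: int
    j: int
    bases: str  # two characters, 5' base then 3' base

    nt = 2


@dataclass(frozen=True)
class BaseItem:
    i: int
    base: str

    nt = 1


def _helix_items(e: Element, seq: str) -> list:
    items = []
    chain = e.closing_pairs
    for k, (i, j) in enumerate(chain):
        items.append(PairItem(i, j, seq[i - 1] + seq[j - 1]))
        if k + 1 < len(chain):
            i2, j2 = chain[k + 1]
            items.extend(BaseItem(p, seq[p - 1]) for p in range(i + 1, i2))
            items.extend(BaseItem(p, seq[p - 1]) for p in range(j2 + 1, j))
    return items


def node_items(node: TreeNode, seq: str):
    """Content of a node as ordered scoring items.

    Helices and hairpins yield one flat item list; junctions yield one list
    per loop region (5'->3').  The virtual root has empty content.
    """
    if node.is_virtual:
        if node.kind == JUNCTION:
            return [[] for _ in range(node.signature.branch_count)]
        return []
    e = node.element
    if e.kind == HELIX:
        return _helix_items(e, seq)
    if e.kind == HAIRPIN:
        return [BaseItem(p, seq[p - 1]) for p in e.nucleotides]
    return [[BaseItem(p, seq[p - 1]) for p in range(a, b + 1)]
            for a, b in e.loop_regions]


def node_nt_count(node: TreeNode) -> int:
    if node.is_virtual:
        return 0
    e = node.element
    if e.kind == HELIX:
        return len(e.nucleotides)  # paired + internal-loop bases
    return len(e.nucleotides)


# ---------------------------------------------------------------------------
# generic global alignment over item lists

def global_align(items1, items2, params: ScoringParams, with_columns: bool = False):
    """Global Needleman-Wunsch over mixed pair/base item lists.

    Returns the score, or ``(score, columns)`` with columns as
    ``(item_or_None, item_or_None)``.  Traceback tie-break: diagonal, then
    gap in the second list, then gap in the first.
    """
    g = params.gap_penalty
    n1, n2 = len(items1), len(items2)

    def sub(a, b):
        pa, pb = isinstance(a, PairItem), isinstance(b, PairItem)
        if pa and pb:
            return params.pair_matrix[(a.bases, b.bases)]
        if not pa and not pb:
            return params.single_matrix[(a.base, b.base)]
        return NEG_INF  # pair-vs-single prohibited; gap moves cover 3g

    gap = [None] + [it.nt * g for it in items1]
    gap2 = [None] + [it.nt * g for it in items2]

    prev = [0.0] * (n2 + 1)
    for j in range(1, n2 + 1):
        prev[j] = prev[j - 1] + gap2[j]
    rows = [prev]
    for i in range(1, n1 + 1):
        cur = [rows[-1][0] + gap[i]] + [0.0] * n2
        above = rows[-1]
        for j in range(1, n2 + 1):
            cur[j] = max(above[j - 1] + sub(items1[i - 1], items2[j - 1]),
                         above[j] + gap[i],
                         cur[j - 1] + gap2[j])
        rows.append(cur)
    score = rows[n1][n2]
    if not with_columns:
        return score
    # traceback
    cols = []
    i, j = n1, n2
    while i > 0 or j > 0:
        here = rows[i][j]
        if i > 0 and j > 0 and rows[i - 1][j - 1] + sub(items1[i - 1], items2[j - 1]) == here:
            cols.append((items1[i - 1], items2[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and rows[i - 1][j] + gap[i] == here:
            cols.append((items1[i - 1], None))
            i -= 1
        else:
            cols.append((None, items2[j - 1]))
            j -= 1
    cols.reverse()
    return score, cols


# ---------------------------------------------------------------------------
# gamma

def gamma_gap(node: TreeNode, params: ScoringParams) -> float:
    """Score of matching a node with the empty node: g per nucleotide."""
    return params.gap_penalty * node_nt_count(node)


def gamma_same_type(n1: TreeNode, n2: TreeNode, params: ScoringParams,
                    with_columns: bool = False):
    """Inner alignment score s of two same-type nodes (no junction bonus)."""
    if n1.kind != n2.kind:
        raise ValueError(f"cannot align a {n1.kind} with a {n2.kind}")
    seq1 = _node_seq(n1)
    seq2 = _node_seq(n2)
    if n1.kind == JUNCTION:
        if n1.signature != n2.signature:
            raise ValueError("junction signatures differ")
        regions1 = node_items(n1, seq1)
        regions2 = node_items(n2, seq2)
        assert len(regions1) == len(regions2)
        if not with_columns:
            return sum(global_align(r1, r2, params)
                       for r1, r2 in zip(regions1, regions2))
        total, cols = 0.0, []
        for r1, r2 in zip(regions1, regions2):
            sc, c = global_align(r1, r2, params, with_columns=True)
            total += sc
            cols.extend(c)
        return total, cols
    return global_align(node_items(n1, seq1), node_items(n2, seq2), params,
                        with_columns=with_columns)


def gamma_junction(n1: TreeNode, n2: TreeNode, params: ScoringParams) -> float:
    """Junction-junction gamma: s + w, s + w/2, or -inf on signature mismatch."""
    if n1.kind != JUNCTION or n2.kind != JUNCTION:
        raise ValueError("gamma_junction expects two junction nodes")
    s1, s2 = n1.signature, n2.signature
    if s1 != s2:
        return NEG_INF
    s = gamma_same_type(n1, n2, params)
    if not s1.is_none:  # equal signatures: both patterns are the same motif
        return s + params.junction_weight
    return s + params.junction_weight / 2.0


def _node_seq(node: TreeNode) -> str:
    # each node's element positions index into its own structure's sequence,
    # attached by build_tree
    return "" if node.is_virtual else node._sequence
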