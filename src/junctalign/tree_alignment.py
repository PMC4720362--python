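"""Constrained tree-matching dynamic program over two structure trees.

A two-dimensional table holds, for every pair of post-order positions
(i, j), the best local alignment score S of the subtrees rooted at t1[i]
and t2[j].  Cells are filled bottom-up (post-order guarantees children
before parents) by a nine-way dispatch on the node kinds:

* junction/junction: match the roots (signature equality required, with the
  CHS bonus folded into gamma) plus the position-wise sum over the child
  subtree pairs -- sibling order is significant and children are never
  permuted;
* helix/helix: match the roots and optionally their single child subtrees;
* hairpin/hairpin: match the roots;
* mixed kinds: the cheaper root is gapped and the walk descends past it
  (into the helix child, or into the best junction child).

Every recurrence carries a 0 alternative, so all cells are >= 0 (local
alignment).  The best alignment starts at the maximum cell (smallest i,
then j, on ties) and backtracks until it meets a zero-valued cell.  The
maximum cell may be an interior subtree pair: the alignment is of subtrees,
not forced to include the roots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decomposition import decompose, HELIX, JUNCTION, HAIRPIN
from .structure_io import SecondaryStructure
from .tree_model import RNATree, TreeNode, build_tree
from . import element_scoring as es
from .element_scoring import NEG_INF, ScoringParams

__all__ = ["ScoreTable", "AlignmentResult", "fill_table", "best_alignment", "align"]


@dataclass
class ScoreTable:
    """Filled DP table plus, per cell, the winning case for backtracking."""

    tree1: RNATree
    tree2: RNATree
    cells: np.ndarray          # shape (|T1|+1, |T2|+1); row/col 0 unused
    case_trace: dict           # (i, j) -> trace tuple
    params: ScoringParams

    def score(self, i: int, j: int) -> float:
        return float(self.cells[i, j])

    def max_cell(self) -> tuple:
        """(i, j) of the maximum cell; ties -> smallest i, then smallest j."""
        sub = self.cells[1:, 1:]
        flat = int(np.argmax(sub))  # row-major argmax is the required tie-break
        i, j = divmod(flat, sub.shape[1])
        return i + 1, j + 1


def fill_table(tree1: RNATree, tree2: RNATree, params: ScoringParams) -> ScoreTable:
    """Compute S(T1[i], T2[j]) for every subtree pair."""
    n1, n2 = len(tree1), len(tree2)
    S = np.zeros((n1 + 1, n2 + 1))
    trace = {}
    gap_cache = {}

    def gap(node: TreeNode) -> float:
        v = gap_cache.get(node)
        if v is None:
            v = gap_cache[node] = es.gamma_gap(node, params)
        return v

    for i in range(1, n1 + 1):
        a = tree1.node(i)
        for j in range(1, n2 + 1):
            b = tree2.node(j)
            # alternatives in tie-break priority order:
            # match first, then subcase 1, then subcase 2 (smallest child k)
            alts = []
            ka, kb = a.kind, b.kind
            if ka == JUNCTION and kb == JUNCTION:
                gj = es.gamma_junction(a, b, params)
                if gj > NEG_INF:  # equal signatures => equal child counts
                    forest = sum(S[ca.post_order, cb.post_order]
                                 for ca, cb in zip(a.children, b.children))
                    alts.append((gj + forest, ("jmatch",)))
            elif ka == HELIX and kb == HELIX:
                gm = es.gamma_same_type(a, b, params)
                child = S[a.children[0].post_order, b.children[0].post_order]
                alts.append((gm + child, ("hmatch", True)))
                alts.append((gm, ("hmatch", False)))
            elif ka == HAIRPIN and kb == HAIRPIN:
                alts.append((es.gamma_same_type(a, b, params), ("pmatch",)))
            elif ka == JUNCTION and kb == HELIX:
                alts.append((gap(b) + S[i, b.children[0].post_order], ("gap2", 0)))
                for k, ca in enumerate(a.children):
                    alts.append((gap(a) + S[ca.post_order, j], ("gap1", k)))
            elif ka == JUNCTION and kb == HAIRPIN:
                for k, ca in enumerate(a.children):
                    alts.append((gap(a) + S[ca.post_order, j], ("gap1", k)))
            elif ka == HELIX and kb == JUNCTION:
                alts.append((gap(a) + S[a.children[0].post_order, j], ("gap1", 0)))
                for k, cb in enumerate(b.children):
                    alts.append((gap(b) + S[i, cb.post_order], ("gap2", k)))
            elif ka == HELIX and kb == HAIRPIN:
                alts.append((gap(a) + S[a.children[0].post_order, j], ("gap1", 0)))
            elif ka == HAIRPIN and kb == JUNCTION:
                for k, cb in enumerate(b.children):
                    alts.append((gap(b) + S[i, cb.post_order], ("gap2", k)))
            elif ka == HAIRPIN and kb == HELIX:
                alts.append((gap(b) + S[i, b.children[0].post_order], ("gap2", 0)))

            best, best_trace = 0.0, ("zero",)
            for value, tr in alts:
                if value > best:  # strict: earlier alternatives win ties
                    best, best_trace = value, tr
            S[i, j] = best
            trace[(i, j)] = best_trace if best > 0 else ("zero",)
    return ScoreTable(tree1, tree2, S, trace, params)


@dataclass
class AlignmentResult:
    """Optimal local alignment of two structure trees.

    ``node_pairs`` lists matched nodes in backtrack order; a pair with one
    ``None`` side is a node matched against the empty node.
    ``nucleotide_alignment`` is parallel to ``node_pairs``: per pair, the
    inner alignment columns as 1-based ``(pos1_or_None, pos2_or_None)``.
    """

    score: float
    node_pairs: list
    nucleotide_alignment: list
    start_cell: tuple
    params: ScoringParams
    tree1: RNATree
    tree2: RNATree

    def columns(self):
        """Flat iterator over all nucleotide columns."""
        for cols in self.nucleotide_alignment:
            yield from cols

    def matched_junction_pairs(self) -> list:
        return [(a, b) for a, b in self.node_pairs
                if a is not None and b is not None and a.kind == JUNCTION]

    def summary(self) -> str:
        p = self.params
        out = [f"alignment score: {self.score:.2f}",
               f"start cell: {self.start_cell}",
               f"params: gap={p.gap_penalty:g} w={p.junction_weight:g} "
               f"matrix={p.matrix_id}",
               "node pairs (kind, node1, node2, gamma):"]
        seq1, seq2 = self.tree1.sequence, self.tree2.sequence
        for (a, b), cols in zip(self.node_pairs, self.nucleotide_alignment):
            kind = (a or b).kind
            la = a.label if a is not None else "-"
            lb = b.label if b is not None else "-"
            if a is not None and b is not None:
                if kind == JUNCTION:
                    g = es.gamma_junction(a, b, p)
                else:
                    g = es.gamma_same_type(a, b, p)
            else:
                g = es.gamma_gap(a if a is not None else b, p)
            out.append(f"  {kind:8s} {la:>5s} {lb:>5s} {g:9.2f}")
            row1 = "".join(seq1[c[0] - 1] if c[0] else "-" for c in cols)
            row2 = "".join(seq2[c[1] - 1] if c[1] else "-" for c in cols)
            if row1 or row2:
                out.append(f"           {row1}")
                out.append(f"           {row2}")
        return "\n".join(out) + "\n"

    def to_json(self) -> dict:
        pairs = []
        for (a, b), cols in zip(self.node_pairs, self.nucleotide_alignment):
            pairs.append({
                "kind": (a or b).kind,
                "node1": a.label if a is not None else None,
                "node2": b.label if b is not None else None,
                "columns": [[c[0], c[1]] for c in cols],
            })
        return {"score": round(self.score, 2),
                "start_cell": list(self.start_cell),
                "params": {"gap_penalty": self.params.gap_penalty,
                           "junction_weight": self.params.junction_weight,
                           "matrix": self.params.matrix_id},
                "node_pairs": pairs}


def _all_gap_columns(node: TreeNode, side: int) -> list:
    items = es.node_items(node, "" if node.is_virtual else node._sequence)
    if node.kind == JUNCTION:
        items = [it for region in items for it in region]
    cols = []
    for it in items:
        positions = (it.i, it.j) if isinstance(it, es.PairItem) else (it.i,)
        for pos in positions:
            cols.append((pos, None) if side == 0 else (None, pos))
    return cols


def _match_columns(a: TreeNode, b: TreeNode, params: ScoringParams) -> list:
    _, item_cols = es.gamma_same_type(a, b, params, with_columns=True)
    cols = []
    for x, y in item_cols:
        if isinstance(x, es.PairItem) or isinstance(y, es.PairItem):
            cols.append((x.i if x else None, y.i if y else None))
            cols.append((x.j if x else None, y.j if y else None))
        else:
            cols.append((x.i if x else None, y.i if y else None))
    return cols


def best_alignment(table: ScoreTable) -> AlignmentResult:
    """Backtrack from the maximum cell until a zero-valued step."""
    t1, t2, params = table.tree1, table.tree2, table.params
    start = table.max_cell()
    score = table.score(*start)
    node_pairs, nt_alignment = [], []

    def emit(i: int, j: int):
        if table.cells[i, j] <= 0:
            return
        a, b = t1.node(i), t2.node(j)
        tr = table.case_trace[(i, j)]
        kind = tr[0]
        if kind == "jmatch":
            node_pairs.append((a, b))
            nt_alignment.append(_match_columns(a, b, params))
            for ca, cb in zip(a.children, b.children):
                emit(ca.post_order, cb.post_order)
        elif kind == "hmatch":
            node_pairs.append((a, b))
            nt_alignment.append(_match_columns(a, b, params))
            if tr[1]:
                emit(a.children[0].post_order, b.children[0].post_order)
        elif kind == "pmatch":
            node_pairs.append((a, b))
            nt_alignment.append(_match_columns(a, b, params))
        elif kind == "gap1":
            node_pairs.append((a, None))
            nt_alignment.append(_all_gap_columns(a, 0))
            emit(a.children[tr[1]].post_order, j)
        elif kind == "gap2":
            node_pairs.append((None, b))
            nt_alignment.append(_all_gap_columns(b, 1))
            emit(i, b.children[tr[1]].post_order)

    if score > 0:
        emit(*start)
        total = 0.0
        for a, b in node_pairs:
            if a is not None and b is not None:
                total += (es.gamma_junction(a, b, params) if a.kind == JUNCTION
                          else es.gamma_same_type(a, b, params))
            else:
                total += es.gamma_gap(a if a is not None else b, params)
        assert abs(total - score) < 1e-6, "traceback score mismatch"
    return AlignmentResult(score, node_pairs, nt_alignment, start, params, t1, t2)


def align(s1: SecondaryStructure, annotations1,
          s2: SecondaryStructure, annotations2,
          params: ScoringParams | None = None) -> AlignmentResult:
    """End-to-end pipeline: decompose, build trees, fill the table, backtrack."""
    if params is None:
        params = ScoringParams.default()
    t1 = build_tree(decompose(s1), annotations1)
    t2 = build_tree(decompose(s2), annotations2)
    table = fill_table(t1, t2, params)
    return best_alignment(table)
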