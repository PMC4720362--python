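"""Junction-alignment precision and batch evaluation.

A junction J1 of structure 1 is *aligned with* junction J2 of structure 2
when at least one nucleotide on a loop region of J1 sits in an alignment
column with a nucleotide on a loop region of J2.  Such a junction alignment
is a true positive when the two junctions have the same branch count and
the same coaxial helical stacking status (equal signatures), and a false
positive otherwise.  Precision is PR = TP / (TP + FP); when no junction
alignment exists the denominator is zero and PR is undefined (None) and
excluded from averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import pandas as pd

from .decomposition import JUNCTION
from .tree_alignment import AlignmentResult

__all__ = ["PrecisionReport", "junction_alignment_pairs", "precision",
           "pooled_precision", "mean_precision", "count_pairwise_alignments",
           "batch_report"]


@dataclass(frozen=True)
class PrecisionReport:
    tp: int
    fp: int

    @property
    def pr(self) -> float | None:
        total = self.tp + self.fp
        return None if total == 0 else self.tp / total


def _position_to_junction(tree) -> dict:
    lookup = {}
    for node in tree.nodes:
        if node.kind == JUNCTION and not node.is_virtual:
            for pos in node.element.nucleotides:  # loop-region bases only
                lookup[pos] = node
    return lookup


def junction_alignment_pairs(result: AlignmentResult) -> list:
    """All (J1, J2) node pairs with >= 1 aligned loop-nucleotide pair."""
    j1 = _position_to_junction(result.tree1)
    j2 = _position_to_junction(result.tree2)
    seen, pairs = set(), []
    for p1, p2 in result.columns():
        if p1 is None or p2 is None:
            continue
        a, b = j1.get(p1), j2.get(p2)
        if a is not None and b is not None and (a, b) not in seen:
            seen.add((a, b))
            pairs.append((a, b))
    return pairs


def precision(pairs) -> PrecisionReport:
    """Count TP/FP over junction pairs by signature equality."""
    tp = sum(1 for a, b in pairs if a.signature == b.signature)
    return PrecisionReport(tp=tp, fp=len(pairs) - tp)


def pooled_precision(reports) -> PrecisionReport:
    """Pool TP/FP counts across many alignments."""
    return PrecisionReport(tp=sum(r.tp for r in reports),
                           fp=sum(r.fp for r in reports))


def mean_precision(reports) -> float | None:
    """Unweighted mean of the defined per-alignment PR values."""
    defined = [r.pr for r in reports if r.pr is not None]
    return sum(defined) / len(defined) if defined else None


def count_pairwise_alignments(group_sizes) -> int:
    """Number of within-group pairwise alignments: sum of C(size, 2)."""
    return sum(comb(int(s), 2) for s in group_sizes)


def batch_report(records) -> pd.DataFrame:
    """Tabulate (pair_id, AlignmentResult) records as a TSV-ready frame."""
    rows = []
    for pair_id, result in records:
        rep = precision(junction_alignment_pairs(result))
        rows.append({"pair": pair_id, "score": round(result.score, 2),
                     "TP": rep.tp, "FP": rep.fp,
                     "PR": rep.pr if rep.pr is not None else float("nan")})
    return pd.DataFrame(rows, columns=["pair", "score", "TP", "FP", "PR"])
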