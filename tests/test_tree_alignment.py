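"""The nine-case constrained tree-matching dynamic program."""

import numpy as np
import pytest

from junctalign import (
    align, best_alignment, build_tree, decompose, fill_table, gamma_same_type,
    generate_pair, generate_structure, parse_annotation, random_topology,
)
from junctalign.decomposition import HELIX, JUNCTION, HAIRPIN
from conftest import brute_force_tree_alignment


def tree_of(ss, seq, db, ann_text=""):
    ann = parse_annotation(ann_text) if ann_text else []
    return build_tree(decompose(ss(seq, db)), ann)


def test_identical_stem_loops_match_both_nodes(ss, params):
    t = tree_of(ss, "GGGCGAAAGCCC", "((((....))))")
    table = fill_table(t, t, params)
    h, p = t.root, t.root.children[0]
    expected = (gamma_same_type(h, h, params) + gamma_same_type(p, p, params))
    assert table.score(2, 2) == pytest.approx(expected)
    assert table.score(2, 2) == pytest.approx(brute_force_tree_alignment(t, t, params))


def test_self_alignment_is_identity(params):
    s, ann = generate_structure(random_topology(5, degrees=(3, 4)))
    res = align(s, ann, s, ann, params)
    assert res.score > 0
    assert all(a is not None and b is not None
               and a.post_order == b.post_order for a, b in res.node_pairs)
    assert {a.post_order for a, _ in res.node_pairs} == \
        set(range(1, len(res.tree1) + 1))
    for cols in res.nucleotide_alignment:
        assert all(p1 == p2 for p1, p2 in cols)


def test_incompatible_trees_give_empty_alignment(ss, params):
    # single noncanonical GG "helix" with an empty hairpin: every gamma <= 0
    t1 = tree_of(ss, "GG", "()")
    t2 = tree_of(ss, "GG", "()")
    table = fill_table(t1, t2, params)
    res = best_alignment(table)
    assert res.score == 0.0
    assert res.node_pairs == []


def test_all_cells_nonnegative(params):
    (s1, a1), (s2, a2) = generate_pair(random_topology(9), 1, 2)
    t1 = build_tree(decompose(s1), a1)
    t2 = build_tree(decompose(s2), a2)
    table = fill_table(t1, t2, params)
    assert np.all(table.cells >= 0)


def test_junction_vs_helix_cell_takes_best_subcase(ss, params):
    # three-way tree against a plain stem-loop: the junction/helix cell must
    # equal the better of (skip the helix) and (descend into one child)
    t1 = tree_of(ss, "GGGGAAGCGCAAAAGCGCAGGGCAAAAGCCCAACCCC",
                 "((((..((((....)))).((((....))))..))))", "J1 H1H3\n")
    t2 = tree_of(ss, "GCGCAAAAGCGC", "((((....))))")
    table = fill_table(t1, t2, params)
    (j,) = [n for n in t1.nodes if n.kind == JUNCTION]
    helix_root = t2.root
    i, jdx = j.post_order, helix_root.post_order
    from junctalign.element_scoring import gamma_gap
    sub1 = gamma_gap(helix_root, params) + table.score(i, helix_root.children[0].post_order)
    sub2 = max(gamma_gap(j, params) + table.score(c.post_order, jdx)
               for c in j.children)
    assert table.score(i, jdx) == pytest.approx(max(sub1, sub2, 0.0))


def test_swapped_inputs_score_identically(params):
    for seed in range(6):
        (s1, a1), (s2, a2) = generate_pair(random_topology(seed), seed, seed + 100)
        r12 = align(s1, a1, s2, a2, params)
        r21 = align(s2, a2, s1, a1, params)
        assert r12.score == pytest.approx(r21.score)


def test_matched_junctions_always_share_signature(params):
    for seed in range(10):
        (s1, a1), _ = generate_pair(random_topology(seed, max_depth=2), seed, 0)
        (s2, a2), _ = generate_pair(random_topology(seed + 50, max_depth=2),
                                    seed + 1, 0)
        res = align(s1, a1, s2, a2, params)
        for a, b in res.matched_junction_pairs():
            assert a.signature == b.signature


def test_score_non_decreasing_in_weight(params):
    (s1, a1), (s2, a2) = generate_pair(random_topology(2, degrees=(3,)), 3, 4)
    scores = [align(s1, a1, s2, a2, params.with_weight(w)).score
              for w in (0.0, 25.0, 100.0, 400.0)]
    assert scores == sorted(scores)


def test_dp_equals_enumeration_on_small_instances(params):
    hits = 0
    for seed in range(15):
        (s1, a1), (s2, a2) = generate_pair(
            random_topology(seed, degrees=(3,)), seed, seed + 7)
        t1 = build_tree(decompose(s1), a1)
        t2 = build_tree(decompose(s2), a2)
        if len(t1) > 6 or len(t2) > 6:
            continue
        table = fill_table(t1, t2, params)
        res = best_alignment(table)
        assert res.score == pytest.approx(brute_force_tree_alignment(t1, t2, params))
        hits += 1
    assert hits >= 5


def test_deterministic_traceback(params):
    (s1, a1), (s2, a2) = generate_pair(random_topology(4), 8, 9)
    r1 = align(s1, a1, s2, a2, params)
    r2 = align(s1, a1, s2, a2, params)
    assert r1.score == r2.score
    assert [(a.post_order if a else None, b.post_order if b else None)
            for a, b in r1.node_pairs] == \
        [(a.post_order if a else None, b.post_order if b else None)
         for a, b in r2.node_pairs]
    assert r1.nucleotide_alignment == r2.nucleotide_alignment


def test_max_cell_tie_break_smallest_indices(params):
    t = build_tree(decompose(generate_structure(random_topology(1))[0]),
                   generate_structure(random_topology(1))[1])
    table = fill_table(t, t, params)
    i, j = table.max_cell()
    best = table.cells[1:, 1:].max()
    cells = [(a, b) for a in range(1, len(t) + 1) for b in range(1, len(t) + 1)
             if table.cells[a, b] == best]
    assert (i, j) == min(cells)


def test_gap_matched_nodes_emit_all_gap_columns(ss, params):
    # a stem-loop whose helix matches t2's outer helix and whose hairpin
    # matches a hairpin below t2's junction: the optimal alignment must gap
    # t2's junction node and one branch helix on the way down
    t1 = tree_of(ss, "GCGCGCGGGGCCCCUUUUGCGCGC",
                 "((((((............))))))")
    t2 = tree_of(ss, "GCGCGCAAAAAAUAAGGGGCCCCUUUUUAGCGCGC",
                 "((((((.(....).(............).))))))", "J1 none\n")
    res = best_alignment(fill_table(t1, t2, params))
    gap_nodes = [(a, b) for a, b in res.node_pairs if a is None or b is None]
    assert gap_nodes  # the junction and a branch helix must be skipped
    assert any(b is not None and b.kind == JUNCTION for _, b in gap_nodes)
    for (a, b), cols in zip(res.node_pairs, res.nucleotide_alignment):
        if b is None:
            assert all(c[1] is None and c[0] is not None for c in cols)
            assert len(cols) == len(a.element.nucleotides)
        if a is None:
            assert all(c[0] is None and c[1] is not None for c in cols)
            assert len(cols) == len(b.element.nucleotides)


def test_report_outputs(params):
    (s1, a1), (s2, a2) = generate_pair(random_topology(6), 1, 2)
    res = align(s1, a1, s2, a2, params)
    text = res.summary()
    assert f"{res.score:.2f}" in text
    doc = res.to_json()
    assert doc["score"] == pytest.approx(res.score, abs=0.005)
    assert len(doc["node_pairs"]) == len(res.node_pairs)
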