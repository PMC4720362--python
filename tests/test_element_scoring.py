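"""Gamma scoring of node contents under RIBOSUM85-60."""

import math
import random

import pytest

from junctalign import (
    NEG_INF, ScoringParams, build_tree, decompose, gamma_gap, gamma_junction,
    gamma_same_type, generate_structure, parse_annotation, random_topology,
)
from junctalign import element_scoring as es
from junctalign.decomposition import HELIX, JUNCTION, HAIRPIN
from conftest import brute_force_global_align


def tree_of(ss, seq, db, ann_text=""):
    ann = parse_annotation(ann_text) if ann_text else []
    return build_tree(decompose(ss(seq, db)), ann)


def node_of(tree, kind, which=0):
    return [n for n in tree.nodes if n.kind == kind][which]


class TestMatrixAsset:
    def test_blocks_complete_and_symmetric(self, params):
        assert len(params.single_matrix) == 16
        assert len(params.pair_matrix) == 256
        for (a, b), v in params.single_matrix.items():
            assert params.single_matrix[(b, a)] == v
        for (a, b), v in params.pair_matrix.items():
            assert params.pair_matrix[(b, a)] == v

    def test_param_validation(self, params):
        with pytest.raises(ValueError):
            ScoringParams(params.single_matrix, params.pair_matrix, gap_penalty=0.5)
        with pytest.raises(ValueError):
            ScoringParams(params.single_matrix, params.pair_matrix,
                          junction_weight=-1)


class TestGammaGap:
    def test_hairpin_counts_loop_bases(self, ss, params):
        t = tree_of(ss, "GCAAAAAGC", "((.....))")
        assert gamma_gap(node_of(t, HAIRPIN), params) == -5.0

    def test_helix_pairs_count_two_nucleotides_each(self, ss, params):
        t = tree_of(ss, "GGGCAAAGCCC", "(((.....)))")
        assert gamma_gap(node_of(t, HELIX), params) == -6.0

    def test_virtual_root_is_free(self, ss, params):
        t = tree_of(ss, "GGAAACCGGAAACC", "((...))((...))")
        assert t.root.is_virtual
        assert gamma_gap(t.root, params) == 0.0


class TestGammaSameType:
    def test_identical_hairpins_score_diagonal(self, ss, params):
        t = tree_of(ss, "GCGAAAGC", "((....))")
        p = node_of(t, HAIRPIN)
        expected = sum(params.single_matrix[(b, b)] for b in "GAAA")
        assert gamma_same_type(p, p, params) == pytest.approx(expected)

    def test_hairpin_against_empty_loop_is_all_gaps(self, ss, params):
        t1 = tree_of(ss, "GCGAAAGC", "((....))")
        t2 = tree_of(ss, "GC", "()")
        score = gamma_same_type(node_of(t1, HAIRPIN), node_of(t2, HAIRPIN), params)
        assert score == pytest.approx(-4.0)

    def test_helix_diagonal_beats_all_alignments(self, ss, params):
        t1 = tree_of(ss, "GCAAAAGC", "((....))")   # pairs GC, CG
        t2 = tree_of(ss, "GAAAAAUC", "((....))")   # pairs GC, AU
        h1, h2 = node_of(t1, HELIX), node_of(t2, HELIX)
        got = gamma_same_type(h1, h2, params)
        expected = (params.pair_matrix[("GC", "GC")]
                    + params.pair_matrix[("CG", "AU")])
        assert got == pytest.approx(expected)
        items1 = es.node_items(h1, t1.sequence)
        items2 = es.node_items(h2, t2.sequence)
        assert got == pytest.approx(brute_force_global_align(items1, items2, params))

    def test_helix_with_internal_loop_mixes_items(self, ss, params):
        t1 = tree_of(ss, "GGACGAAAACGCC", "((.((....))))")
        t2 = tree_of(ss, "GGCGAAAACGCC", "((((....))))")
        h1, h2 = node_of(t1, HELIX), node_of(t2, HELIX)
        items1 = es.node_items(h1, t1.sequence)
        items2 = es.node_items(h2, t2.sequence)
        assert sum(isinstance(i, es.BaseItem) for i in items1) == 1  # the bulge
        got = gamma_same_type(h1, h2, params)
        assert got == pytest.approx(brute_force_global_align(items1, items2, params))

    def test_type_mismatch_rejected(self, ss, params):
        t = tree_of(ss, "GGGCAAAGCCC", "(((.....)))")
        with pytest.raises(ValueError):
            gamma_same_type(node_of(t, HELIX), node_of(t, HAIRPIN), params)

    def test_symmetry_and_self_dominance_on_random_nodes(self, params):
        rng = random.Random(0)
        nodes = {HELIX: [], JUNCTION: [], HAIRPIN: []}
        for seed in range(8):
            s, ann = generate_structure(random_topology(seed, degrees=(3,)))
            t = build_tree(decompose(s), ann)
            for n in t.nodes:
                nodes[n.kind].append(n)
        for kind in (HELIX, HAIRPIN):
            for _ in range(20):
                a, b = rng.choice(nodes[kind]), rng.choice(nodes[kind])
                sab = gamma_same_type(a, b, params)
                assert sab == pytest.approx(gamma_same_type(b, a, params))
        # canonical-pair contents: a node's self-score is the diagonal sum and
        # dominates its score against any same-type node of equal length
        for kind in (HELIX, HAIRPIN):
            for n in nodes[kind]:
                items = es.node_items(n, n._sequence)
                diag = sum(params.pair_matrix[(i.bases, i.bases)]
                           if isinstance(i, es.PairItem)
                           else params.single_matrix[(i.base, i.base)]
                           for i in items)
                self_score = gamma_same_type(n, n, params)
                assert self_score == pytest.approx(diag)
                same_len = [m for m in nodes[kind]
                            if es.node_nt_count(m) == es.node_nt_count(n)]
                for m in same_len:
                    assert gamma_same_type(n, m, params) <= self_score + 1e-9


class TestGammaJunction:
    def make_junctions(self, ss, ann1, ann2):
        seq = "GGGGAAGCGCAAAAGCGCAGGGCAAAAGCCCAACCCC"
        db = "((((..((((....)))).((((....))))..))))"
        t1 = tree_of(ss, seq, db, ann1)
        t2 = tree_of(ss, seq, db, ann2)
        return node_of(t1, JUNCTION), node_of(t2, JUNCTION)

    def test_matching_motifs_add_full_weight(self, ss, params):
        j1, j2 = self.make_junctions(ss, "J1 H1H3\n", "J1 H1H3\n")
        s = gamma_same_type(j1, j2, params)
        assert gamma_junction(j1, j2, params) == pytest.approx(s + 100.0)

    def test_both_none_add_half_weight(self, ss, params):
        j1, j2 = self.make_junctions(ss, "J1 none\n", "J1 none\n")
        s = gamma_same_type(j1, j2, params)
        assert gamma_junction(j1, j2, params) == pytest.approx(s + 50.0)

    def test_different_motifs_prohibited(self, ss, params):
        j1, j2 = self.make_junctions(ss, "J1 H1H2\n", "J1 H2H3\n")
        assert gamma_junction(j1, j2, params) == NEG_INF
        with pytest.raises(ValueError):
            gamma_same_type(j1, j2, params)

    def test_different_branch_count_prohibited(self, ss, params):
        s3, a3 = generate_structure(random_topology(3, degrees=(3,)))
        s4, a4 = generate_structure(random_topology(4, degrees=(4,)))
        j3 = node_of(build_tree(decompose(s3), a3), JUNCTION)
        j4 = node_of(build_tree(decompose(s4), a4), JUNCTION)
        assert gamma_junction(j3, j4, params) == NEG_INF

    def test_junction_regions_align_region_wise(self, ss, params):
        j1, j2 = self.make_junctions(ss, "J1 H1H3\n", "J1 H1H3\n")
        regions1 = es.node_items(j1, j1._sequence)
        regions2 = es.node_items(j2, j2._sequence)
        expected = sum(brute_force_global_align(r1, r2, params)
                       for r1, r2 in zip(regions1, regions2))
        assert gamma_same_type(j1, j2, params) == pytest.approx(expected)


def test_neg_inf_sentinel_annihilates():
    assert NEG_INF + 5.0 == NEG_INF
    assert max(NEG_INF, 0.0) == 0.0
    assert not math.isnan(NEG_INF + 1e9)
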