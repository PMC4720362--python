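# junctalign

Junction-aware pairwise alignment of RNA secondary structures with
coaxial helical stacking constraints.

## The problem

RNA multi-branch loops (junctions) organize the global fold of structured
RNAs, and within a junction two helices frequently stack coaxially
(a CHS motif, written HxHy for stacked helices x and y), forming a
pseudocontiguous helix that shapes the molecule's 3D architecture.
Classical secondary-structure aligners compare sequences and base pairs
but are blind to this tertiary feature, so they happily align a three-way
junction stacked H1H2 onto one stacked H2H3 — two arrangements with very
different geometry.  `junctalign` is for structural bioinformaticians who
want structure comparison that respects junction architecture: it aligns
two pseudoknot-free secondary structures under the hard constraint that a
junction may only be matched to a junction with the same number of
branches *and* the same CHS pattern.

## The method

Each input structure R (bpseq or dot-bracket) is decomposed into typed
elements — helices (runs of nested base pairs absorbing internal loops
and bulges), n-way junctions (n ≥ 3), and hairpin loops — and transformed
into an ordered labeled tree T: the first helix 5'→3' around an n-way
junction is the junction node's parent and the other n−1 helices are its
children in 5'→3' order, so hairpins are leaves and a helix has exactly
one child.  Nodes carry post-order indices t[i].

The aligner fills a |T1|×|T2| table whose cell (i, j) holds
S(T1[i], T2[j]), the best local alignment score of the two subtrees,
via a nine-case recurrence on the node kinds.  Only same-kind nodes can
match; a matched node pair is scored by γ, a global Needleman–Wunsch
alignment of the node contents under RIBOSUM85-60 (4×4 block for unpaired
bases, 16×16 block for base pairs, linear gap penalty g = −1 per
nucleotide).  For junctions with equal signature Ψ (branch count + CHS
pattern), γ gains a bonus: s + w when both junctions carry a CHS motif
and s + w/2 when both are unstacked, with w = 100 by default; junctions
with different signatures score −∞ and can never match.  Mismatched kinds
force one node to be gapped (γ = g per nucleotide) while the walk
descends past it.  Every recurrence includes a 0 alternative, so the
alignment is local: the result starts at the maximum cell and backtracks
until it meets a zero.

Junction *precision* of an alignment is PR = TP/(TP+FP), where a junction
alignment (two junctions sharing at least one aligned loop-nucleotide
pair) is a true positive iff the junctions agree in branch count and CHS
status.  Because signature equality is a hard constraint of the matcher,
alignments produced with correct annotations have FP = 0 by construction,
i.e. PR = 1 whenever any junction pair exists.

Annotations reach the aligner in two modes: **u-mode** (the user supplies
a `.chs` file per structure: `J1 H1H3`, `J2 H1H4 H2H3`, `J3 none`) or
**p-mode** (an external predictor command is run per structure on a bpseq
file and must print the same grammar on stdout).

## Worked example

Generate a seeded synthetic pair (same topology, resampled sequences,
light loop noise on the second copy) and align it in u-mode:

```sh
junctalign generate --seed 11 --out-prefix demo --perturb
junctalign align demo_1.bpseq demo_2.bpseq --annotation demo_1.chs demo_2.chs
```

```
alignment score: 187.35
start cell: (16, 16)
params: gap=-1 w=100 matrix=RIBOSUM85-60
node pairs (kind, node1, node2, gamma):
  helix       H1    H1      5.56
           UAGU
           UAAU
  junction    J1    J1     40.37
           -UUCAUUGG-AUU
           GCU-GCGUAGA--
  ...
  junction    J2    J2     92.54
           CA-GAGGCAAACGGA-
           CAC-UUUUUGAU-AAC
  ...
junction precision: TP=2 FP=0 PR=1.00
```

The score is the sum of the per-node γ values along the traceback.  The
unstacked three-way junction J1 matched J1 for 40.37 (its loop-alignment
score plus w/2 = 50 minus mismatches), the H1H4-stacked four-way junction
J2 matched J2 with the full +100 bonus, and both junction alignments are
true positives (PR = 1), as the constraint guarantees.  Aligning two
structures with *conflicting* annotations (say H1H3 vs H1H2 on the same
molecule) removes the junction match entirely and the score collapses to
whatever the helices and hairpins alone support.

The same pipeline is available as a library:

```python
import junctalign as ja

s1 = ja.parse_bpseq(open("demo_1.bpseq").read())
ann1 = ja.parse_annotation(open("demo_1.chs").read())
s2 = ja.parse_bpseq(open("demo_2.bpseq").read())
ann2 = ja.parse_annotation(open("demo_2.chs").read())
res = ja.align(s1, ann1, s2, ann2)
print(res.score)                      # 187.35
rep = ja.precision(ja.junction_alignment_pairs(res))
print(rep.tp, rep.fp, rep.pr)         # 2 0 1.0
```

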