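# Methods

## Model

A pseudoknot-free secondary structure R over sequence R_seq (bases
A/C/G/U, 1-based positions, at least one base pair) is decomposed into
three element types:

* **helix** — a maximal chain of nested base pairs in which consecutive
  pairs enclose only unpaired bases.  Internal loops and bulges are part
  of the helix, never elements of their own: a loop bordered by exactly
  two pairs is by definition not a junction (n must exceed 2).
* **n-way junction** — an enclosed loop bordered by n ≥ 3 pairs: the
  closing pair (i1, j1) of the enclosing helix plus the outer pairs
  (i2, j2)…(in, jn) of the n−1 enclosed helices.  Its loop regions are
  R_seq[i1+1, i2−1], R_seq[j2+1, i3−1], …, R_seq[jn+1, j1−1] in 5'→3'
  order; regions may be empty.
* **hairpin loop** — the unpaired interior of a pair that encloses no
  other pair.

Membership is disjoint: junctions and hairpins own only unpaired bases;
all base pairs belong to helices.  Bases exterior to every pair belong to
no element and are never scored — the tree model has no node that could
hold them, and this package keeps that property rather than invent one.

The element set becomes an ordered labeled tree: the first helix 5'→3'
around a junction is the junction node's parent, the other n−1 helices
its children in 5'→3' order, so a junction node has degree n−1, a helix
node exactly one child, and hairpins are leaves.  Post-order indices are
assigned children-first, which places a helix's only child at
index(helix)−1.

Each junction carries a signature Ψ = (branch count, CHS pattern), the
CHS pattern being a set of unordered stacked-helix index pairs {x, y}
with helices numbered 1..n from the parent helix in 5'→3' order; the
empty set is status "none".  For three-way junctions this reduces to the
classic four-state encoding Π ∈ {H1H2, H2H3, H1H3, none}.  Signature
equality for arbitrary n is defined as equality of branch count and of
the full canonicalized pattern set, the only generalization of the
three-way case that preserves the scoring split below.

## Scoring

γ(node, node) is a global Needleman–Wunsch alignment of node contents
with linear gap cost g per nucleotide (default −1) and RIBOSUM85-60
substitution scores:

* hairpins: one alignment of the loop sequences (4×4 block);
* junctions: loop region k aligns with loop region k, independently,
  summed over k.  Signature equality guarantees equal region counts;
  regions are never cross-matched, which keeps loop strands in their
  structural context;
* helices: one alignment over the ordered item list — base pairs
  outer→inner (16×16 block) with internal-loop/bulge bases interleaved at
  their 5'-strand positions (5'-side bases before 3'-side bases between
  consecutive pairs).  Pair-vs-single matches are prohibited; since
  gapping a pair costs 2g and a single g, prohibition is implemented by
  leaving only the gap moves, which price such a column at 3g.

γ(node, ∅) = g × (nucleotide count), a base pair counting twice.
Junction–junction γ adds the stacking bonus: s + w when Ψ are equal and
both junctions carry a motif, s + w/2 when Ψ are equal and both are
"none", −∞ otherwise.  −∞ is the IEEE infinity: it annihilates sums and
loses every max, which is exactly the algebra the case analysis needs,
with no overflow or threshold artifacts.

The tree DP fills S(T1[i], T2[j]) bottom-up by kind dispatch
(junction/junction matches roots plus children strictly position-wise;
helix/helix matches roots and optionally child subtrees;
hairpin/hairpin matches roots; the six mixed cases gap the unmatched
root and descend past it — into a helix's only child, or into the
junction child maximizing the score).  Every case carries a 0
alternative.  The result is the maximum cell (ties: smallest i, then j),
backtracked until a zero-valued cell ends each branch of the trace.
Runtime is O(|R1|×|R2|): the per-cell work is dominated by the γ inner
alignments, and element sizes sum to the sequence lengths.

## Parameters

| parameter | default | meaning |
|---|---|---|
| g (gap penalty) | −1 per nucleotide | linear gap cost in every inner alignment and for node-vs-∅ |
| w (junction weight) | 100 | bonus for matching two CHS-stacked junctions with equal signature; w/2 when both are unstacked; w > 50 is the regime where junction anchoring dominates |
| matrix | RIBOSUM85-60 | 4×4 single-base + 16×16 base-pair log-odds blocks; any file in the same two-block format can be substituted (`--matrix`) |

Scores are real-valued and displayed to two decimals (w/2 with odd w is
fractional by design).

The embedded RIBOSUM85-60 asset (`src/junctalign/data/ribosum85_60.mat`)
is transcribed from the published RSEARCH (Klein & Eddy 2003)
distribution; the file stores the upper triangles and the loader
symmetrizes.  Because the matrix allows all 16 pair types, noncanonical
pairs in the input are handled without special cases.

## Design choices made where the design was open

* **Junction loop regions align region-wise**, not concatenated.  The
  alternative (concatenating all regions into one strand before aligning)
  admits alignments that slide bases across branch boundaries; since
  signature equality already fixes the region correspondence, the
  region-wise form was chosen.  This choice shifts absolute scores of
  junction-rich alignments relative to any implementation that
  concatenated, and is the main documented source of uncertainty in
  reproducing third-party absolute score values.
* **Helix internal-loop bases are scored inside γ** as single-base items
  in the helix item list (the other defensible option is to ignore them);
  this keeps every interior nucleotide of the molecule scoreable.
* **Ties** in the DP prefer the matching alternative, then the first
  subcase, then the smaller child index; the inner alignments prefer the
  diagonal.  The pseudoknot cleaner prefers the lexicographically
  smallest sorted pair list among maximum-cardinality non-crossing
  subsets.  All outputs are therefore deterministic for fixed inputs.
* **Multi-domain structures** (more than one outermost helix) get a
  virtual root: a content-free pseudo-junction over the domains with
  branch count (domains + 1) and pattern "none".  Single-domain inputs
  never create it.  This is an extension beyond the single-domain model;
  its behavior on multi-domain inputs has no external reference.
* **Pseudoknot fallback**: crossing inputs are cleaned to a
  maximum-cardinality non-crossing subset of the existing pairs
  (interval DP over the pairs).  Dedicated pseudoknot-removal tools can
  use different criteria (e.g. maximizing kept helices or stems), so the
  fallback is declared, not claimed equivalent to any of them.
* **Degenerate inputs**: a structure with zero pairs is rejected (the
  model requires at least one); an empty hairpin loop or empty junction
  region is legal and contributes an empty content list; a junction
  signature with branch count < 3 is rejected at construction.

## Synthetic data

The generator (`junctalign.synthetic`) emulates pseudoknot-free
structures assembled from the three element types: prescribed stem
lengths with internal loops/bulges, junction degrees 3–5 with valid CHS
labels (a random stacked pair, two disjoint stacked pairs at degree ≥ 4,
or none), hairpin loops of 3–6 nt, optional nested junctions.  Paired
positions draw uniformly from the six canonical/wobble pair types,
unpaired positions uniformly from ACGU; one `random.Random(seed)` stream
makes output byte-identical across runs.  The perturber resamples loop
bases and applies single-base loop indels without ever touching a paired
base, so topology and CHS labels are invariant by construction.

What it does **not** emulate: thermodynamic plausibility (no energy
model; helix compositions are i.i.d., real helices are not), sequence
covariation between homologs, junction family geometry, higher-order
junctions (> 5-way), or pseudoknots.  Consequently, green tests on
synthetic pairs demonstrate the algorithmic guarantees — constraint
soundness (precision 1 with correct annotations), symmetry,
non-negativity, weight monotonicity, and equivalence with exhaustive
enumeration — but say nothing about alignment *quality* on real
molecules, which depends on how well RIBOSUM85-60 and w reflect real
structural homology.

## Problem sizes used by the checks

The precision check pools 50 pairwise alignments of generated structures
(roughly 40–150 nt each, mixed 3-/4-/5-way junctions, 10% loop
substitutions and 20% per-loop indel probability on the second copy of
each pair).  The enumeration cross-check runs 500 random instances
small enough for exhaustive mapping enumeration (trees of at most 6
nodes, at most 4 nt per element); the invariant suite runs 200 random
pairs at four junction weights.  These sizes make the full suite run in
seconds while exercising every case of the recurrence.

## Known limitations

* Junction children match strictly position-wise; circularly permuted
  junctions score poorly by design, and aligning a p-way with a q-way
  junction (p ≠ q) is out of scope.
* Exterior (inter-domain and terminal) single strands are unscored.
* Only one optimal alignment is reported (deterministic tie-breaks), and
  gaps are linear — there is no affine gap model and no suboptimal or
  partition-function output.
* Absolute score reproduction against third-party outputs depends on the
  matrix transcription and the region-wise junction convention above;
  the regression test for published riboswitch scores requires input
  files that cannot be bundled.
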