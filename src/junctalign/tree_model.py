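"""Ordered labeled tree representation of a decomposed RNA structure.

Each node is a helix, junction or hairpin element.  The first helix in
5'->3' order around an n-way junction is the junction node's *parent*; the
remaining n-1 helices are its children, left-to-right in 5'->3' order, so a
junction node has degree n-1.  Helix nodes have exactly one child (the loop
at their inner end); hairpins are leaves.  Nodes carry 1-based post-order
indices (children before parent), under which a helix node's only child sits
at index(helix) - 1.

Multi-domain structures (two or more outermost helices) get a virtual root:
a zero-content pseudo-junction whose children are the domains in 5'->3'
order; it carries signature branch count (domains + 1) and pattern "none".
Single-domain inputs never create it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .decomposition import ElementSet, Element, HELIX, JUNCTION, HAIRPIN
from .structure_io import CHSAnnotation, AnnotationError

__all__ = ["JunctionSignature", "TreeNode", "RNATree", "build_tree", "signature"]


@dataclass(frozen=True)
class JunctionSignature:
    """Branch count plus canonicalized CHS pattern of a junction.

    Two junctions may be aligned iff their signatures are equal.  ``pi``
    encodes the classic three-way status: 0 none, 1 H1H2, 2 H2H3, 3 H1H3.
    """

    branch_count: int
    chs_pattern: frozenset = frozenset()

    def __post_init__(self):
        if self.branch_count < 3:
            raise ValueError("branch_count must be >= 3")
        for p in self.chs_pattern:
            if max(p) > self.branch_count:
                raise ValueError(
                    f"CHS pattern {set(p)} references a helix index beyond "
                    f"branch count {self.branch_count}")

    @property
    def pi(self) -> int | None:
        """Encoded CHS status for 3-way junctions; None for higher orders."""
        if self.branch_count != 3:
            return None
        table = {frozenset(): 0,
                 frozenset([frozenset((1, 2))]): 1,
                 frozenset([frozenset((2, 3))]): 2,
                 frozenset([frozenset((1, 3))]): 3}
        return table.get(self.chs_pattern)

    @property
    def is_none(self) -> bool:
        return not self.chs_pattern


@dataclass(eq=False)
class TreeNode:
    kind: str
    element: Element | None          # None only for the virtual root
    children: list = field(default_factory=list)
    label: str = ""
    post_order: int = 0
    signature: JunctionSignature | None = None

    @property
    def is_virtual(self) -> bool:
        return self.element is None

    def __repr__(self):
        return f"<TreeNode {self.label or self.kind} #{self.post_order}>"


@dataclass
class RNATree:
    """Post-order indexed ordered labeled tree of one structure."""

    root: TreeNode
    nodes: list                      # nodes[i-1] has post_order == i
    elements: ElementSet

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, post_order: int) -> TreeNode:
        return self.nodes[post_order - 1]

    @property
    def sequence(self) -> str:
        return self.elements.structure.sequence

    def dump(self) -> str:
        out = []

        def walk(n, depth):
            sig = ""
            if n.kind == JUNCTION and n.signature is not None:
                pat = sorted((min(p), max(p)) for p in n.signature.chs_pattern)
                chs = " ".join(f"H{x}H{y}" for x, y in pat) or "none"
                sig = f" [{n.signature.branch_count}-way, {chs}]"
            out.append("  " * depth + f"{n.label or n.kind}#{n.post_order}{sig}")
            for c in n.children:
                walk(c, depth + 1)

        walk(self.root, 0)
        return "\n".join(out) + "\n"

    def newick(self) -> str:
        def walk(n):
            inner = ",".join(walk(c) for c in n.children)
            return (f"({inner})" if inner else "") + (n.label or n.kind)

        return walk(self.root) + ";"


def signature(node: TreeNode) -> JunctionSignature:
    """The junction signature of a junction node."""
    if node.kind != JUNCTION:
        raise ValueError("signature is defined for junction nodes only")
    assert node.signature is not None
    return node.signature


def build_tree(elements: ElementSet, annotations) -> RNATree:
    """Build the ordered labeled tree from elements plus CHS annotations.

    Every junction must carry exactly one annotation (possibly "none"),
    keyed by the 5'->3' junction ids ("J1", "J2", ...) that
    :meth:`ElementSet.junction_ids` assigns.
    """
    jids = elements.junction_ids()
    by_id = {}
    for a in annotations:
        if a.junction_id in by_id:
            raise AnnotationError(f"duplicate annotation for {a.junction_id}")
        by_id[a.junction_id] = a
    known = set(jids.values())
    unknown = set(by_id) - known
    if unknown:
        raise AnnotationError(f"annotation references nonexistent junction(s): "
                              f"{sorted(unknown)} (known: {sorted(known)})")
    missing = known - set(by_id)
    if missing:
        raise AnnotationError(f"junction(s) without annotation: {sorted(missing)}")

    def make(idx: int) -> TreeNode:
        e = elements.elements[idx]
        node = TreeNode(e.kind, e)
        if e.kind == JUNCTION:
            ann = by_id[jids[e]]
            for p in ann.stacked_pairs:
                if max(p) > e.degree:
                    raise AnnotationError(
                        f"{ann.junction_id}: helix index {max(p)} exceeds "
                        f"junction degree {e.degree}")
            node.signature = JunctionSignature(e.degree, ann.stacked_pairs)
            node.label = jids[e]
        node.children = [make(c) for c in elements.children[idx]]
        return node

    domains = [make(i) for i in elements.roots]
    if len(domains) == 1:
        root = domains[0]
    else:
        root = TreeNode(JUNCTION, None, children=domains, label="ROOT",
                        signature=JunctionSignature(len(domains) + 1))

    # post-order numbering and per-kind 5'->3' labels
    nodes = []

    def number(n: TreeNode):
        for c in n.children:
            number(c)
        nodes.append(n)
        n.post_order = len(nodes)

    number(root)
    seq = elements.structure.sequence
    for n in nodes:
        n._sequence = seq  # lets scoring resolve item bases without the tree
    counters = {HELIX: 0, HAIRPIN: 0}
    for n in sorted((n for n in nodes if not n.is_virtual), key=lambda n: n.element.start):
        if n.kind == HELIX:
            counters[HELIX] += 1
            n.label = f"H{counters[HELIX]}"
        elif n.kind == HAIRPIN:
            counters[HAIRPIN] += 1
            n.label = f"P{counters[HAIRPIN]}"
    return RNATree(root, nodes, elements)
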