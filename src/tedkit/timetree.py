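"""Dated-tree data model and tree-geometry operations.

A :class:`TimeTree` is a strictly binary rooted tree whose nodes carry ages in
Ma before present (present = 0, increasing into the past).  Extant tips sit at
age exactly 0; fossil tips sit at fixed positive ages.  Branch *durations* are
``parent.age - child.age``.  Every prior density and likelihood in the package
scores this object.

Tip labels are the identity key: taxon matching is exact and case-sensitive.
Polytomies are rejected rather than arbitrarily resolved, because the tree
prior densities assume binary trees.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import dendropy

__all__ = [
    "Node",
    "TimeTree",
    "CladeConstraint",
    "FossilTable",
    "crown_age",
    "prune_fossils",
    "youngest_split_age",
    "ghost_excess",
    "satisfies_constraint",
]

AGE_TOL = 1e-9


class Node:
    """A node of a :class:`TimeTree`; tips carry a label and a tip kind."""

    __slots__ = ("parent", "children", "age", "label", "is_fossil")

    def __init__(self, age: float = 0.0, label: str | None = None,
                 is_fossil: bool = False):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.age = float(age)
        self.label = label
        self.is_fossil = bool(is_fossil)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "fossil" if self.is_fossil else ("tip" if self.is_tip else "node")
        return f"<Node {kind} label={self.label!r} age={self.age:.4g}>"


class TimeTree:
    """Rooted, binary, dated tree.

    Parameters
    ----------
    root
        Root node of an existing node structure.  The tree takes ownership.
    validate
        If true (default), check the structural invariants: binary internal
        nodes, parent ages strictly exceeding child ages, extant tips at age
        0, fossil tips at positive ages, unique tip labels.
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- iteration ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    def extant_tips(self) -> list[Node]:
        return [n for n in self.tips() if not n.is_fossil]

    def fossil_tips(self) -> list[Node]:
        return [n for n in self.tips() if n.is_fossil]

    def taxa(self) -> list[str]:
        return [t.label for t in self.tips()]

    def tip(self, label: str) -> Node:
        for t in self.tips():
            if t.label == label:
                return t
        raise KeyError(f"unknown taxon {label!r}")

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.preorder():
            if node.is_tip:
                if node.label is None:
                    raise ValueError("tip without a label")
                if node.label in seen:
                    raise ValueError(f"duplicate taxon label {node.label!r}")
                seen.add(node.label)
                if node.is_fossil:
                    if node.age <= 0:
                        raise ValueError(
                            f"fossil tip {node.label!r} must have age > 0")
                elif abs(node.age) > AGE_TOL:
                    raise ValueError(
                        f"extant tip {node.label!r} must have age 0, "
                        f"got {node.age}")
                else:
                    node.age = 0.0
            else:
                if len(node.children) != 2:
                    raise ValueError(
                        "polytomies/unary nodes are rejected: internal node "
                        f"with {len(node.children)} children")
                for child in node.children:
                    if not node.age > child.age + AGE_TOL * 0:
                        if node.age <= child.age:
                            raise ValueError(
                                "internal node age must strictly exceed "
                                f"child age ({node.age} <= {child.age})")
        if self.root.parent is not None:
            raise ValueError("root must not have a parent")

    # -- copying -----------------------------------------------------------
    def copy(self) -> "TimeTree":
        def clone(node: Node) -> Node:
            new = Node(node.age, node.label, node.is_fossil)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return TimeTree(clone(self.root), validate=False)

    # -- MRCA / geometry ---------------------------------------------------
    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        labels = set(labels)
        if not labels:
            raise ValueError("empty taxon set")
        known = set(self.taxa())
        for lab in labels:
            if lab not in known:
                raise KeyError(f"unknown taxon {lab!r}")
        # count, for every node, how many target tips it subtends
        counts: dict[int, int] = {}
        node_by_id: dict[int, Node] = {}
        for node in self.postorder():
            node_by_id[id(node)] = node
            if node.is_tip:
                counts[id(node)] = 1 if node.label in labels else 0
            else:
                counts[id(node)] = sum(counts[id(c)] for c in node.children)
        target = len(labels)
        best: Node = self.root
        for node in self.postorder():
            if counts[id(node)] == target:
                best = node
                break
        return best

    def total_duration(self) -> float:
        """Sum of branch durations over the whole tree (Myr)."""
        return sum(n.parent.age - n.age for n in self.preorder()
                   if n.parent is not None)

    # -- Newick ------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, fossil_ages: Mapping[str, float] | None = None,
                    tol: float = 1e-6) -> "TimeTree":
        """Build a dated tree from a Newick string with branch lengths in Myr.

        Node ages are recovered from tip dates plus branch lengths: tips named
        in ``fossil_ages`` are fossils at the given positive ages, all other
        tips are extant at age 0.  Inconsistent path lengths (beyond ``tol``)
        are rejected.
        """
        fossil_ages = dict(fossil_ages or {})
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True)
        droot = dtree.seed_node

        def convert(dnode) -> Node:
            if not dnode.child_nodes():
                label = dnode.taxon.label if dnode.taxon else dnode.label
                if label is None:
                    raise ValueError("unlabelled tip in Newick input")
                age = float(fossil_ages.get(label, 0.0))
                return Node(age, label, is_fossil=label in fossil_ages)
            node = Node()
            implied = []
            for dchild in dnode.child_nodes():
                child = convert(dchild)
                edge = dchild.edge.length
                if edge is None:
                    raise ValueError("Newick input must have branch lengths")
                implied.append(child.age + float(edge))
                node.add_child(child)
            if max(implied) - min(implied) > tol:
                raise ValueError(
                    f"inconsistent node age from children: {implied}")
            node.age = sum(implied) / len(implied)
            return node

        return cls(convert(droot))

    def to_newick(self, precision: int = 8) -> str:
        """Newick string with branch lengths in Myr."""

        def render(node: Node) -> str:
            if node.is_tip:
                core = node.label
            else:
                core = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.parent is None:
                return core
            bl = node.parent.age - node.age
            return f"{core}:{bl:.{precision}g}"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<TimeTree {self.n_tips} tips "
                f"({len(self.fossil_tips())} fossil), "
                f"root age {self.root.age:.4g} Ma>")


@dataclass(frozen=True)
class CladeConstraint:
    """A named hard monophyly constraint on a set of extant taxa.

    The constraint applies to the fossil-pruned tree only: fossils may attach
    anywhere, inside or outside the constrained clade.
    """

    name: str
    taxa: frozenset[str]
    hard: bool = True

    def __post_init__(self):
        if not self.taxa:
            raise ValueError("constraint taxon set must be non-empty")
        object.__setattr__(self, "taxa", frozenset(self.taxa))


@dataclass
class FossilTable:
    """Map taxon -> fossil age (Ma); fixed point values with no uncertainty."""

    ages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for taxon, age in self.ages.items():
            if not age > 0:
                raise ValueError(f"fossil age for {taxon!r} must be > 0")

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.ages

    def __getitem__(self, taxon: str) -> float:
        return self.ages[taxon]

    def __len__(self) -> int:
        return len(self.ages)

    def items(self):
        return self.ages.items()

    @property
    def oldest_age(self) -> float:
        return max(self.ages.values()) if self.ages else 0.0

    @classmethod
    def from_tsv(cls, path_or_buf) -> "FossilTable":
        """Read a two-column (taxon, age) tab-separated table."""
        if isinstance(path_or_buf, (str,)):
            fh = open(path_or_buf)
            close = True
        else:
            fh, close = path_or_buf, False
        try:
            ages = {}
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                taxon, age = line.split("\t")
                if taxon in ages:
                    raise ValueError(f"duplicate fossil taxon {taxon!r}")
                ages[taxon] = float(age)
        finally:
            if close:
                fh.close()
        return cls(ages)

    def to_tsv(self, path_or_buf) -> None:
        buf = io.StringIO()
        for taxon, age in sorted(self.ages.items()):
            buf.write(f"{taxon}\t{age:.6g}\n")
        if isinstance(path_or_buf, str):
            with open(path_or_buf, "w") as fh:
                fh.write(buf.getvalue())
        else:
            path_or_buf.write(buf.getvalue())


# ---------------------------------------------------------------------------
# tree-geometry operations
# ---------------------------------------------------------------------------

def crown_age(tree: TimeTree, taxa: Iterable[str]) -> float:
    """Age (Ma) of the most recent common ancestor of the given extant taxa.

    Fossils are pruned before locating the crown node, so a fossil nested
    inside the clade does not alter the crown age.
    """
    taxa = set(taxa)
    pruned = prune_fossils(tree) if tree.fossil_tips() else tree
    for lab in taxa:
        if lab not in set(pruned.taxa()):
            raise KeyError(f"unknown taxon {lab!r}")
    if len(taxa) == 1:
        return pruned.tip(next(iter(taxa))).age
    return pruned.mrca(taxa).age


def prune_fossils(tree: TimeTree) -> TimeTree:
    """Remove fossil tips and suppress resulting degree-2 nodes.

    Ages along extant paths are unchanged, so all pairwise extant distances
    are preserved.  Idempotent.
    """
    if len(tree.extant_tips()) < 2:
        raise ValueError("need at least 2 extant tips to prune fossils")
    work = tree.copy()

    def build(node: Node) -> Node | None:
        if node.is_tip:
            if node.is_fossil:
                return None
            return Node(node.age, node.label, False)
        kids = [build(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]  # suppress degree-2 node; child keeps its age
        new = Node(node.age)
        for k in kids:
            new.add_child(k)
        return new

    root = build(work.root)
    assert root is not None
    # a pruned root may have become unary at the top
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    return TimeTree(root)


def youngest_split_age(tree: TimeTree) -> float:
    """Minimum internal-node age among nodes subtending >= 2 extant tips.

    This is the diversified-sampling cutoff x_cut: the age of the most recent
    split in the sampled extant tree, beyond which no more lineages are
    sampled.
    """
    if len(tree.extant_tips()) < 2:
        raise ValueError("need at least 2 extant tips")
    n_extant: dict[int, int] = {}
    best = None
    for node in tree.postorder():
        if node.is_tip:
            n_extant[id(node)] = 0 if node.is_fossil else 1
        else:
            n_extant[id(node)] = sum(n_extant[id(c)] for c in node.children)
            kids_with = sum(1 for c in node.children if n_extant[id(c)] >= 1)
            if kids_with >= 2:  # a genuine split in the extant tree
                if best is None or node.age < best:
                    best = node.age
    assert best is not None
    return best


def ghost_excess(tree: TimeTree, fossils: FossilTable | None = None) -> float:
    """Total implied ghost-lineage duration (Myr), a DRA diagnostic.

    Sum over internal nodes of (node age - age of the oldest sampled
    descendant of that node).  Sampled descendants are the tree's own tips
    (extant at 0, fossils at their fixed ages).  The value is 0 exactly when
    every internal node age equals its oldest sampled descendant's age, i.e.
    for a maximally compressed tree; it grows as divergences are pushed into
    strata unobserved in the fossil record.
    """
    oldest: dict[int, float] = {}
    total = 0.0
    for node in tree.postorder():
        if node.is_tip:
            age = node.age
            if fossils is not None and node.label in fossils:
                age = fossils[node.label]
            oldest[id(node)] = age
        else:
            oldest[id(node)] = max(oldest[id(c)] for c in node.children)
            total += node.age - oldest[id(node)]
    return total


def satisfies_constraint(tree: TimeTree, constraint: CladeConstraint) -> bool:
    """True iff the constraint's extant taxa are monophyletic after pruning
    fossils.  Fossils may attach anywhere without violating the constraint."""
    pruned = prune_fossils(tree) if tree.fossil_tips() else tree
    extant = set(pruned.taxa())
    for lab in constraint.taxa:
        if lab not in extant:
            raise KeyError(f"unknown taxon {lab!r}")
    node = pruned.mrca(constraint.taxa)
    subtended = {t.label for t in TimeTree(node, validate=False).tips()} \
        if not node.is_tip else {node.label}
    return subtended == set(constraint.taxa)
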