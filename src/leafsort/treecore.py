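"""Merge-tree data model for agglomerative clustering results.

A dendrogram is a rooted binary tree of ``n - 1`` merges over ``n`` items.
Each internal node carries the dissimilarity (height) at which its two
children merged; the left/right order of children is significant, because it
encodes the drawn orientation and hence the leaf order — the object every
ordering heuristic in this package manipulates.

Conventions
-----------
* Leaves have ids ``0 .. n-1`` in input-matrix order and height 0.
* Internal nodes have ids ``n .. 2n-2`` in merge order.
* Heights live on nodes (ultrametric style); Newick serialization converts
  them to edge lengths (child edge = parent height - child height).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterator, Sequence

__all__ = [
    "LeafsortError",
    "ValidationError",
    "NewickParseError",
    "Node",
    "MergeTree",
    "MergeTable",
    "ValidationReport",
    "from_merge_table",
    "to_merge_table",
    "leaf_order",
    "to_newick",
    "from_newick",
    "validate",
    "subtree_profile",
]


class LeafsortError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(LeafsortError):
    """A structural invariant of a tree, table, or matrix is violated."""


class NewickParseError(LeafsortError):
    """Newick text could not be parsed into a binary height tree."""


@dataclass
class Node:
    """One node of a merge tree.

    Leaves carry ``label`` and ``index`` (0-based position in the input
    matrix); internal nodes carry ``left``/``right`` children and a merge
    ``height`` in the units of the input dissimilarities.
    """

    id: int
    height: float = 0.0
    left: "Node | None" = None
    right: "Node | None" = None
    label: str | None = None
    index: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def copy(self) -> "Node":
        if self.is_leaf:
            return Node(self.id, self.height, None, None, self.label, self.index)
        return Node(self.id, self.height, self.left.copy(), self.right.copy())


class MergeTree:
    """A rooted binary merge tree; thin wrapper around the root :class:`Node`."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def leaves(self) -> Iterator[Node]:
        """Leaves in current left-to-right order."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.append(node.right)
                stack.append(node.left)

    def internal_nodes(self) -> Iterator[Node]:
        """Internal nodes in postorder (children before parents)."""
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.append(node.left)
                stack.append(node.right)
        return iter(reversed(out))

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    @property
    def labels(self) -> list[str]:
        """Leaf labels in input-index order when indices are present,
        otherwise in current leaf order."""
        leaves = list(self.leaves())
        if all(l.index is not None for l in leaves):
            leaves.sort(key=lambda l: l.index)
        return [l.label for l in leaves]

    def copy(self) -> "MergeTree":
        return MergeTree(self.root.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MergeTree(n_leaves={self.n_leaves})"


@dataclass
class MergeTable:
    """Flat encoding of a merge tree: ``n - 1`` rows ``(child_a, child_b, height)``.

    Row ``i`` defines internal node ``n + i``; ids ``0 .. n-1`` reference
    leaves in input order, ids ``n ..`` reference earlier rows. ``child_a``
    becomes the left child, ``child_b`` the right child.
    """

    merges: list[tuple[int, int, float]]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @classmethod
    def from_linkage(cls, Z, labels: Sequence[str]) -> "MergeTable":
        """Build from a scipy-style linkage matrix (first two columns are
        children ids, third is the merge height)."""
        merges = [(int(a), int(b), float(h)) for a, b, h, *_ in Z]
        return cls(merges, list(labels))


def from_merge_table(table: MergeTable) -> MergeTree:
    """Construct a :class:`MergeTree` from a :class:`MergeTable`.

    Child order in each row is preserved (``child_a`` left, ``child_b``
    right). Raises :class:`ValidationError` naming the offending row on
    duplicate child references, dangling ids, or negative/non-finite heights.
    """
    n = table.n_leaves
    if n < 1:
        raise ValidationError("merge table has no leaf labels")
    if len(table.merges) != n - 1:
        raise ValidationError(
            f"expected {n - 1} merge rows for {n} leaves, got {len(table.merges)}"
        )
    if len(set(table.labels)) != n:
        raise ValidationError("duplicate leaf labels in merge table")

    nodes: dict[int, Node] = {
        i: Node(i, 0.0, label=lab, index=i) for i, lab in enumerate(table.labels)
    }
    used: set[int] = set()
    for row, (a, b, h) in enumerate(table.merges):
        node_id = n + row
        if a == b:
            raise ValidationError(f"row {row}: duplicate child reference {a}")
        for child in (a, b):
            if child not in nodes or child >= node_id:
                raise ValidationError(f"row {row}: dangling child id {child}")
            if child in used:
                raise ValidationError(f"row {row}: child {child} already merged")
        if not math.isfinite(h) or h < 0:
            raise ValidationError(f"row {row}: invalid height {h!r}")
        used.update((a, b))
        nodes[node_id] = Node(node_id, float(h), nodes[a], nodes[b])
    root = nodes[2 * n - 2] if n > 1 else nodes[0]
    return MergeTree(root)


def to_merge_table(tree: MergeTree) -> MergeTable:
    """Flatten a tree back to a merge table.

    Rows are emitted in non-decreasing height order subject to the
    child-before-parent constraint, with ties broken by the nodes' existing
    ids (stable with respect to the original merge order). Leaf ids follow
    input indices when present, otherwise left-to-right leaf order.
    """
    leaves = list(tree.leaves())
    n = len(leaves)
    if all(l.index is not None for l in leaves):
        order_key = {id(l): l.index for l in leaves}
    else:
        order_key = {id(l): pos for pos, l in enumerate(leaves)}
    new_id = {id(l): order_key[id(l)] for l in leaves}
    labels = [None] * n
    for l in leaves:
        labels[new_id[id(l)]] = l.label

    internals = list(tree.internal_nodes())
    pending = {id(node): sum(1 for c in (node.left, node.right) if not c.is_leaf)
               for node in internals}
    parent: dict[int, Node] = {}
    for node in internals:
        for c in (node.left, node.right):
            if not c.is_leaf:
                parent[id(c)] = node
    ready = [(node.height, node.id, id(node), node)
             for node in internals if pending[id(node)] == 0]
    heapq.heapify(ready)
    merges: list[tuple[int, int, float]] = []
    while ready:
        _, _, _, node = heapq.heappop(ready)
        merges.append((new_id[id(node.left)], new_id[id(node.right)], node.height))
        new_id[id(node)] = n + len(merges) - 1
        par = parent.get(id(node))
        if par is not None:
            pending[id(par)] -= 1
            if pending[id(par)] == 0:
                heapq.heappush(ready, (par.height, par.id, id(par), par))
    return MergeTable(merges, labels)


def leaf_order(tree: MergeTree) -> list[str]:
    """Leaf labels read left to right — the linear order the dendrogram induces."""
    return [l.label for l in tree.leaves()]


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def to_newick(tree: MergeTree) -> str:
    """Serialize to Newick with branch lengths.

    A child's branch length is ``parent height - child height`` (leaves sit
    at height 0); the root carries no length. Labels containing Newick
    metacharacters are single-quoted.
    """

    def esc(label: str) -> str:
        if any(c in label for c in "(),:;'[] \t"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def rec(node: Node, parent_height: float | None) -> str:
        if node.is_leaf:
            body = esc(node.label)
        else:
            body = f"({rec(node.left, node.height)},{rec(node.right, node.height)})"
        if parent_height is None:
            return body
        return f"{body}:{_fmt(parent_height - node.height)}"

    return rec(tree.root, None) + ";"


def from_newick(text: str) -> MergeTree:
    """Parse Newick text into a :class:`MergeTree`.

    The tree must be strictly binary with non-negative branch lengths.
    Node heights are reconstructed as ``max root-to-leaf distance`` minus the
    node's distance from the root; leaf heights are snapped to exactly 0
    (non-ultrametric input is tolerated and surfaced by :func:`validate`).
    Leaf input indices are assigned in left-to-right order.
    """
    from Bio import Phylo

    try:
        bio_tree = Phylo.read(StringIO(text), "newick")
    except Exception as exc:  # Bio raises bare NewickError without position
        raise NewickParseError(f"unparseable Newick text: {exc}") from exc

    depths: dict[int, float] = {}

    def depth_of(clade, d: float) -> None:
        length = clade.branch_length
        if length is None:
            length = 0.0
        if length < 0:
            raise NewickParseError(
                f"negative branch length {length} at node {clade.name!r}"
            )
        d += length
        depths[id(clade)] = d
        for c in clade.clades:
            depth_of(c, d)

    root_clade = bio_tree.root
    root_clade.branch_length = root_clade.branch_length or 0.0
    depth_of(root_clade, 0.0)
    max_depth = max(depths[id(c)] for c in bio_tree.get_terminals())

    counter = {"leaf": 0, "internal": 0}
    n_leaves = len(bio_tree.get_terminals())

    def build(clade) -> Node:
        kids = clade.clades
        if not kids:
            idx = counter["leaf"]
            counter["leaf"] += 1
            label = clade.name if clade.name is not None else f"leaf{idx}"
            return Node(idx, 0.0, label=label, index=idx)
        if len(kids) != 2:
            raise NewickParseError(
                f"non-binary node with {len(kids)} children at {clade.name!r}"
            )
        left = build(kids[0])
        right = build(kids[1])
        node_id = n_leaves + counter["internal"]
        counter["internal"] += 1
        return Node(node_id, max_depth - depths[id(clade)], left, right)

    return MergeTree(build(root_clade))


def subtree_profile(tree: MergeTree) -> set[tuple[frozenset, float]]:
    """The multiset-free signature ``{(leaf label set, height)}`` over internal
    nodes. Orientation-only operations leave this invariant."""
    out: set[tuple[frozenset, float]] = set()

    def rec(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        s = rec(node.left) | rec(node.right)
        out.add((s, node.height))
        return s

    rec(tree.root)
    return out


@dataclass
class ValidationReport:
    """Diagnostic summary from :func:`validate`; never raises."""

    n_leaves: int
    n_internal: int
    monotonicity_violations: int
    duplicate_labels: list[str] = field(default_factory=list)
    zero_height_internal: int = 0
    negative_heights: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            not self.duplicate_labels
            and self.monotonicity_violations == 0
            and self.negative_heights == 0
        )


def validate(tree: MergeTree) -> ValidationReport:
    """Structural diagnostics: counts, height monotonicity (parent >= child
    along every path), duplicate labels, zero/negative heights.

    Monotonicity violations are reported, not rejected: single-linkage ties
    and externally built trees can legitimately be non-strict.
    """
    leaves = list(tree.leaves())
    internals = list(tree.internal_nodes())
    seen: set[str] = set()
    dups: list[str] = []
    for l in leaves:
        if l.label in seen and l.label not in dups:
            dups.append(l.label)
        seen.add(l.label)
    mono = 0
    zero = 0
    neg = 0
    for node in internals:
        if node.height == 0:
            zero += 1
        if node.height < 0 or not math.isfinite(node.height):
            neg += 1
        for c in (node.left, node.right):
            if node.height < c.height:
                mono += 1
    msgs = []
    if dups:
        msgs.append(f"duplicate labels: {dups}")
    if mono:
        msgs.append(f"{mono} parent-below-child height pairs")
    if zero:
        msgs.append(f"{zero} internal nodes at height 0 (tied or duplicate items)")
    if neg:
        msgs.append(f"{neg} negative or non-finite internal heights")
    return ValidationReport(
        n_leaves=len(leaves),
        n_internal=len(internals),
        monotonicity_violations=mono,
        duplicate_labels=dups,
        zero_height_internal=zero,
        negative_heights=neg,
        messages=msgs,
    )


# -- plain-text interchange -------------------------------------------------

MERGE_TABLE_HEADER = "child_a\tchild_b\theight"


def write_merge_table(table: MergeTable, path, label_path) -> None:
    """Write a merge table as TSV (header ``child_a child_b height``) plus a
    one-label-per-line file."""
    with open(path, "w") as fh:
        fh.write(MERGE_TABLE_HEADER + "\n")
        for a, b, h in table.merges:
            fh.write(f"{a}\t{b}\t{_fmt(h)}\n")
    with open(label_path, "w") as fh:
        for lab in table.labels:
            fh.write(lab + "\n")


def read_merge_table(path, label_path) -> MergeTable:
    with open(label_path) as fh:
        labels = [line.rstrip("\n") for line in fh if line.strip() != ""]
    merges: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("child_a"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(f"{path}:{lineno + 1}: expected 3 columns")
            merges.append((int(parts[0]), int(parts[1]), float(parts[2])))
    return MergeTable(merges, labels)
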