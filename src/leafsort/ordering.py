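"""Leaf-ordering heuristics for dendrograms.

A binary merge tree over ``n`` items admits ``2^(n-1)`` leaf orders: the
children of every internal node can be swapped without changing the
clustering itself. This module implements:

* :func:`order_default` — the R-style orientation rules (input order for
  leaf-leaf merges, leaf to the left of a subtree, smaller previous-merge
  height to the left for subtree-subtree merges);
* :func:`order_molo` — modular leaf ordering: place left the subtree whose
  smallest (criterion ``min``) or mean (criterion ``avg``) preceding merge
  height is smaller, treating a lone leaf as having key ``+inf`` so it always
  goes right of a subtree. Each subtree ends up drawn as a right triangle
  growing left to right in merge order;
* :func:`order_gw` — the Gruvaeus–Wainer endpoint heuristic (greedy,
  bottom-up: minimize the distance between the two leaves facing each other
  across every merge);
* :func:`order_olo` — optimal leaf ordering: the dynamic program that
  minimizes the Hamiltonian path length (sum of consecutive leaf distances)
  over all orders reachable by flips;
* :func:`enumerate_flip_orders` — the exhaustive flip oracle for small trees.

All operations return a reoriented copy; topology and heights never change,
and every tie keeps the existing orientation so results are deterministic.
"""

from __future__ import annotations

import math

import numpy as np

from .clustering import DistanceMatrix
from .treecore import LeafsortError, MergeTree, Node, ValidationError

__all__ = [
    "order_default",
    "order_molo",
    "order_gw",
    "order_olo",
    "enumerate_flip_orders",
    "subtree_key",
    "order_by_method",
    "ORDER_METHODS",
]


# ---------------------------------------------------------------------------
# default (R-style) orientation

def order_default(tree: MergeTree) -> MergeTree:
    """Reorient every merge by the default R-style rules.

    leaf + leaf: the leaf earlier in the input matrix goes left.
    leaf + subtree: the leaf goes left.
    subtree + subtree: the subtree formed at the smaller height goes left;
    equal heights keep the current orientation.
    """
    tree = tree.copy()

    def rec(node: Node) -> None:
        if node.is_leaf:
            return
        rec(node.left)
        rec(node.right)
        l, r = node.left, node.right
        if l.is_leaf and r.is_leaf:
            if l.index is None or r.index is None:
                raise ValidationError(
                    "default ordering requires leaf input indices"
                )
            if l.index > r.index:
                node.left, node.right = r, l
        elif l.is_leaf or r.is_leaf:
            if r.is_leaf:  # leaf always left
                node.left, node.right = r, l
        else:
            if l.height > r.height:
                node.left, node.right = r, l

    rec(tree.root)
    return tree


# ---------------------------------------------------------------------------
# modular leaf ordering

def subtree_key(node: Node, criterion: str = "min") -> float:
    """The statistic a merge is ordered by: the minimum (``min``) or
    arithmetic mean (``avg``) of all merge heights inside the subtree.
    Leaves carry the sentinel ``+inf`` — this is what sends a lone leaf to
    the right of any subtree."""
    if node.is_leaf:
        return math.inf
    heights: list[float] = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if not cur.is_leaf:
            heights.append(cur.height)
            stack.append(cur.left)
            stack.append(cur.right)
    if criterion == "min":
        return min(heights)
    if criterion == "avg":
        return sum(heights) / len(heights)
    raise ValidationError(f"unknown criterion {criterion!r}")


def order_molo(tree: MergeTree, criterion: str = "min") -> MergeTree:
    """Modular leaf ordering: at every merge, the child subtree with the
    smaller key (smallest or mean preceding merge height) goes left; a lone
    leaf (key ``+inf``) goes right of any subtree; equal keys keep the
    existing orientation.

    The result places the tightest (or lowest-mean) cluster leftmost inside
    every subtree, so each subtree silhouette is a right triangle that grows
    left to right in the order clusters were merged. Idempotent.
    """
    if criterion not in ("min", "avg"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    tree = tree.copy()
    key: dict[int, float] = {}

    def fill(node: Node) -> tuple[float, float, int]:
        """Returns (min height, sum of heights, count) for the subtree."""
        if node.is_leaf:
            key[id(node)] = math.inf
            return (math.inf, 0.0, 0)
        lo_l, s_l, c_l = fill(node.left)
        lo_r, s_r, c_r = fill(node.right)
        lo = min(lo_l, lo_r, node.height)
        s = s_l + s_r + node.height
        c = c_l + c_r + 1
        key[id(node)] = lo if criterion == "min" else s / c
        return (lo, s, c)

    fill(tree.root)

    def rec(node: Node) -> None:
        if node.is_leaf:
            return
        if key[id(node.left)] > key[id(node.right)]:
            node.left, node.right = node.right, node.left
        rec(node.left)
        rec(node.right)

    rec(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Gruvaeus-Wainer endpoint heuristic

def _mirror(node: Node) -> None:
    if node.is_leaf:
        return
    node.left, node.right = node.right, node.left
    _mirror(node.left)
    _mirror(node.right)


def order_gw(tree: MergeTree, dist: DistanceMatrix) -> MergeTree:
    """Gruvaeus–Wainer ordering: bottom-up, flip children so that the two
    leaves meeting across each merge (rightmost of the left child, leftmost
    of the right child) are as similar as possible.

    At each internal node the four flip combinations are scored by that
    inner-pair distance; ties prefer no flip, then a left-child flip, then
    right, then both. Flipping a child mirrors its whole subtree.
    """
    tree = tree.copy()
    for lab in (l.label for l in tree.leaves()):
        dist.indices([lab])  # raises on missing label

    def rec(node: Node) -> tuple[str, str]:
        if node.is_leaf:
            return (node.label, node.label)
        lL, rL = rec(node.left)
        lR, rR = rec(node.right)
        combos = [
            (dist.get(rL, lR), False, False),
            (dist.get(lL, lR), True, False),
            (dist.get(rL, rR), False, True),
            (dist.get(lL, rR), True, True),
        ]
        best = min(combos, key=lambda c: c[0])  # min is stable: first minimum
        _, flip_l, flip_r = best
        if flip_l:
            _mirror(node.left)
            lL, rL = rL, lL
        if flip_r:
            _mirror(node.right)
            lR, rR = rR, lR
        return (lL, rR)

    rec(tree.root)
    return tree


# ---------------------------------------------------------------------------
# optimal leaf ordering

def order_olo(tree: MergeTree, dist: DistanceMatrix, cap: int = 2000) -> MergeTree:
    """Optimal leaf ordering: among all ``2^(n-1)`` flip orders, return one
    minimizing the Hamiltonian path length (sum of distances between
    consecutive leaves).

    Dynamic program over states ``(subtree, leftmost leaf, rightmost leaf)``:
    ``cost(V, l, r) = min over splits of cost(L, l, m) + d(m, k) + cost(R, k, r)``.
    Ties at the root resolve toward the input orientation. ``cap`` bounds the
    problem size (the DP is cubic in ``n``); beyond it, use the MOLO or GW
    heuristics instead.
    """
    tree = tree.copy()
    leaves = list(tree.leaves())
    n = len(leaves)
    if n > cap:
        raise LeafsortError(
            f"optimal leaf ordering capped at n={cap} (got {n}); "
            "use molo-min/molo-avg/gw for larger trees"
        )
    if n == 1:
        return tree
    D = dist.values[np.ix_(dist.indices([l.label for l in leaves]),
                           dist.indices([l.label for l in leaves]))]

    idx_of = {id(l): i for i, l in enumerate(leaves)}
    span: dict[int, list[int]] = {}   # node -> local leaf indices, current order
    M: dict[int, np.ndarray] = {}     # node -> cost matrix over its span

    def fill(node: Node) -> None:
        if node.is_leaf:
            span[id(node)] = [idx_of[id(node)]]
            M[id(node)] = np.zeros((1, 1))
            return
        fill(node.left)
        fill(node.right)
        la, lb = span[id(node.left)], span[id(node.right)]
        MA, MB = M[id(node.left)], M[id(node.right)]
        dAB = D[np.ix_(la, lb)]
        a, b = len(la), len(lb)
        # C[l, r] = min_{m,k} MA[l, m] + d(m, k) + MB[k, r], chunked over l
        # to bound memory at ~chunk * a * b floats.
        C = np.empty((a, b))
        chunk = max(1, 4_000_000 // max(1, a * b))
        for s in range(0, a, chunk):
            T = (MA[s:s + chunk, :, None] + dAB[None, :, :]).min(axis=1)
            C[s:s + chunk] = (T[:, :, None] + MB[None, :, :]).min(axis=1)
        full = np.full((a + b, a + b), np.inf)
        full[:a, a:] = C
        full[a:, :a] = C.T
        span[id(node)] = la + lb
        M[id(node)] = full

    fill(tree.root)

    local = {id(node): {g: i for i, g in enumerate(span[id(node)])}
             for node in list(tree.internal_nodes())}
    for l in leaves:
        local[id(l)] = {idx_of[id(l)]: 0}

    def rebuild(node: Node, l: int, r: int) -> None:
        """Reorient the subtree so its leaf path runs from leaf l to leaf r."""
        if node.is_leaf:
            return
        left_set = set(span[id(node.left)])
        if l in left_set:
            A, B = node.left, node.right
        else:
            A, B = node.right, node.left
            node.left, node.right = A, B
        la, lb = span[id(A)], span[id(B)]
        MA, MB = M[id(A)], M[id(B)]
        li, ri = local[id(A)][l], local[id(B)][r]
        vals = MA[li, :][:, None] + D[np.ix_(la, lb)] + MB[:, ri][None, :]
        mi, ki = divmod(int(np.argmin(vals)), len(lb))
        rebuild(A, l, la[mi])
        rebuild(B, lb[ki], r)

    root = tree.root
    full = M[id(root)]
    a = len(span[id(root.left)])
    # Any optimal path has a mirror image of equal cost, so an optimum
    # starting inside the current left child always exists: restricting to
    # that block keeps ties resolved toward the input orientation.
    sub = full[:a, a:]
    li, ri = divmod(int(np.argmin(sub)), full.shape[0] - a)
    l, r = span[id(root)][li], span[id(root)][a + ri]
    rebuild(root, l, r)
    return tree


# ---------------------------------------------------------------------------
# exhaustive oracle

def enumerate_flip_orders(tree: MergeTree, max_leaves: int = 16) -> list[tuple[str, ...]]:
    """All ``2^(n-1)`` leaf orders reachable by flipping merges. Exponential —
    guarded at ``max_leaves`` (default 16); this is the oracle the heuristics
    are validated against on small trees."""
    n = tree.n_leaves
    if n > max_leaves:
        raise LeafsortError(f"enumerate_flip_orders guarded at n={max_leaves} (got {n})")
    internals = list(tree.internal_nodes())
    pos = {id(node): i for i, node in enumerate(internals)}
    orders: list[tuple[str, ...]] = []

    def collect(node: Node, mask: int, out: list[str]) -> None:
        if node.is_leaf:
            out.append(node.label)
            return
        a, b = node.left, node.right
        if mask >> pos[id(node)] & 1:
            a, b = b, a
        collect(a, mask, out)
        collect(b, mask, out)

    for mask in range(1 << len(internals)):
        out: list[str] = []
        collect(tree.root, mask, out)
        orders.append(tuple(out))
    return orders


# ---------------------------------------------------------------------------
# dispatch

ORDER_METHODS = ("default", "molo-min", "molo-avg", "gw", "olo")


def order_by_method(tree: MergeTree, method: str,
                    dist: DistanceMatrix | None = None) -> MergeTree:
    """Apply an ordering method by its CLI name. ``gw`` and ``olo`` require a
    distance matrix; the others ignore it."""
    if method == "default":
        return order_default(tree)
    if method == "molo-min":
        return order_molo(tree, "min")
    if method == "molo-avg":
        return order_molo(tree, "avg")
    if method in ("gw", "olo"):
        if dist is None:
            raise ValidationError(f"method {method!r} requires a distance matrix")
        return order_gw(tree, dist) if method == "gw" else order_olo(tree, dist)
    raise ValidationError(f"unknown ordering method {method!r}")
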