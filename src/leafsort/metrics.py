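"""Quantitative evaluation of leaf orderings.

Three families of measures:

* drawn-ink: the total length of line segments needed to draw the
  dendrogram under a fixed layout (leaves at unit spacing, heights in raw
  dissimilarity units). Risers (height-direction segments) are identical for
  every orientation of the same tree, so orderings differ only in the
  connector (leaf-direction) ink — the quantity behind the data-ink ratio;
* Hamiltonian path length: the seriation loss, the sum of distances between
  consecutive leaves in the order;
* anti-Robinson events: the seriation merit deficit — the number of ordered
  triples whose distances violate the pattern of dissimilarity growing away
  from the diagonal of the reordered distance matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .clustering import DistanceMatrix
from .treecore import MergeTree, Node, ValidationError, leaf_order

__all__ = [
    "LineLengthReport",
    "line_length",
    "data_ink_ratio",
    "path_length",
    "anti_robinson_events",
    "OrderingComparison",
    "compare_orderings",
]


@dataclass(frozen=True)
class LineLengthReport:
    """Decomposition of a dendrogram's drawn ink.

    ``height_direction_total`` sums the riser segments (in dissimilarity
    units) and is invariant under flips; ``leaf_direction_total`` sums the
    connector spans (in leaf-index units, unit leaf spacing).
    """

    height_direction_total: float
    leaf_direction_total: float

    @property
    def total(self) -> float:
        return self.height_direction_total + self.leaf_direction_total


def line_length(tree: MergeTree) -> LineLengthReport:
    """Total drawn line length under the standard layout: leaves at positions
    ``1..n`` (unit spacing), internal node x = midpoint of its children,
    per merge one connector spanning the children plus two risers dropping
    to the children's heights."""
    pos: dict[int, float] = {}
    x = 0.0
    for leaf in tree.leaves():
        x += 1.0
        pos[id(leaf)] = x
    risers = 0.0
    spans = 0.0

    def rec(node: Node) -> float:
        if node.is_leaf:
            return pos[id(node)]
        nonlocal risers, spans
        xl = rec(node.left)
        xr = rec(node.right)
        spans += abs(xr - xl)
        risers += (node.height - node.left.height) + (node.height - node.right.height)
        mid = (xl + xr) / 2.0
        pos[id(node)] = mid
        return mid

    rec(tree.root)
    return LineLengthReport(height_direction_total=risers, leaf_direction_total=spans)


def data_ink_ratio(report: LineLengthReport, baseline: LineLengthReport) -> float:
    """Ratio of total drawn ink to a baseline drawing's ink (< 1 means the
    ordering needs less ink than the baseline)."""
    if baseline.total <= 0:
        raise ValidationError("baseline total line length must be > 0")
    return report.total / baseline.total


def path_length(dist: DistanceMatrix, order) -> float:
    """Hamiltonian path length: sum of ``d(o_i, o_{i+1})`` along the order."""
    order = list(order)
    if sorted(order) != sorted(dist.labels):
        raise ValidationError("order is not a permutation of the distance labels")
    idx = dist.indices(order)
    return float(dist.values[idx[:-1], idx[1:]].sum())


def anti_robinson_events(dist: DistanceMatrix, order) -> int:
    """Count anti-Robinson events in the reordered distance matrix.

    Over every triple of positions ``i < j < k``: one event if
    ``d(o_i,o_j) > d(o_i,o_k)`` and one if ``d(o_j,o_k) > d(o_i,o_k)`` —
    within each row, distances should not decrease moving away from the
    diagonal. 0 for a perfect Robinson matrix.
    """
    order = list(order)
    if sorted(order) != sorted(dist.labels):
        raise ValidationError("order is not a permutation of the distance labels")
    idx = dist.indices(order)
    D = dist.values[np.ix_(idx, idx)]
    n = len(order)
    events = 0
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            tail = D[i, j + 1:]
            events += int((D[i, j] > tail).sum())
            events += int((D[j, j + 1:] > tail).sum())
    return events


@dataclass
class MethodResult:
    """Per-method bundle of the comparison table."""

    method: str
    order: list[str]
    line: LineLengthReport
    ratio_to_default: float
    path_length: float
    anti_robinson: int


@dataclass
class OrderingComparison:
    """Benchmark table over ordering methods for one tree + distance matrix."""

    results: dict[str, MethodResult]

    def to_json(self, indent: int = 2) -> str:
        payload = {
            m: {
                "order": r.order,
                "total_length": r.line.total,
                "height_direction_total": r.line.height_direction_total,
                "leaf_direction_total": r.line.leaf_direction_total,
                "ratio_to_default": r.ratio_to_default,
                "path_length": r.path_length,
                "anti_robinson_events": r.anti_robinson,
            }
            for m, r in self.results.items()
        }
        return json.dumps(payload, indent=indent)

    def to_tsv(self) -> str:
        lines = ["method\ttotal_length\tratio_to_default\tpath_length\tanti_robinson_events"]
        for m, r in self.results.items():
            lines.append(
                f"{m}\t{r.line.total:.2f}\t{r.ratio_to_default:.2f}"
                f"\t{r.path_length:.4f}\t{r.anti_robinson}"
            )
        return "\n".join(lines) + "\n"


def compare_orderings(tree: MergeTree, dist: DistanceMatrix,
                      methods=None) -> OrderingComparison:
    """Run several ordering methods on one tree and tabulate their metrics.

    The ink ratio is always relative to the default (R-style) orientation of
    the same tree, whether or not ``default`` is among the requested methods.
    """
    from .ordering import ORDER_METHODS, order_by_method

    if methods is None:
        methods = list(ORDER_METHODS)
    bad = [m for m in methods if m not in ORDER_METHODS]
    if bad:
        raise ValidationError(f"unknown method(s): {bad}")
    baseline = line_length(order_by_method(tree, "default", dist))
    results: dict[str, MethodResult] = {}
    for m in methods:
        ordered = order_by_method(tree, m, dist)
        rep = line_length(ordered)
        order = leaf_order(ordered)
        results[m] = MethodResult(
            method=m,
            order=order,
            line=rep,
            ratio_to_default=data_ink_ratio(rep, baseline),
            path_length=path_length(dist, order),
            anti_robinson=anti_robinson_events(dist, order),
        )
    return OrderingComparison(results)
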