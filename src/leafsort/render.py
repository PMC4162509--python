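"""SVG rendering of dendrograms and cluster heat maps.

SVG is assembled as plain text with stable element ordering and fixed
numeric formatting, so identical inputs yield byte-identical documents —
the rendering is regression-testable by snapshot.

The dendrogram geometry matches :func:`leafsort.metrics.line_length`:
leaves at unit spacing, internal nodes at the midpoint of their children,
one connector plus two risers per merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treecore import MergeTree, Node, ValidationError, leaf_order

__all__ = ["render_dendrogram", "render_heatmap", "diverging_color"]

_F = "{:.2f}".format  # fixed coordinate formatting for byte stability

# categorical palette for annotation strips (colorblind-safe-ish)
ANNOTATION_PALETTE = [
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a",
    "#66a61e", "#e6ab02", "#a6761d", "#666666",
]


def diverging_color(value: float, vmin: float, vmax: float) -> str:
    """Blue-white-red diverging scale: ``vmin`` maps to blue, the midpoint of
    the limits to white, ``vmax`` to red. Values outside the limits clamp."""
    if vmax <= vmin:
        raise ValidationError("color scale requires vmax > vmin")
    t = (float(value) - vmin) / (vmax - vmin)
    t = min(1.0, max(0.0, t))
    blue = (33, 102, 172)
    white = (255, 255, 255)
    red = (178, 24, 43)
    if t <= 0.5:
        a, b, u = blue, white, t / 0.5
    else:
        a, b, u = white, red, (t - 0.5) / 0.5
    rgb = tuple(round(a[i] + (b[i] - a[i]) * u) for i in range(3))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _svg_open(width: float, height: float) -> str:
    return (
        '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_F(width)}" height="{_F(height)}" '
        f'viewBox="0 0 {_F(width)} {_F(height)}">'
    )


@dataclass
class _DendroGeom:
    """Scaled layout of one dendrogram inside a pixel box."""

    leaf_px: dict[int, float]       # id(leaf) -> along-leaf-axis pixel
    node_px: dict[int, tuple[float, float]]  # id(node) -> (leaf-axis, height-axis)
    step: float                     # pixels per leaf slot


def _layout(tree: MergeTree, extent: float, depth: float) -> _DendroGeom:
    leaves = list(tree.leaves())
    n = len(leaves)
    step = extent / n
    leaf_px = {id(l): (i + 0.5) * step for i, l in enumerate(leaves)}
    max_h = max((nd.height for nd in tree.internal_nodes()), default=1.0) or 1.0
    node_px: dict[int, tuple[float, float]] = {}

    def rec(node: Node) -> float:
        if node.is_leaf:
            x = leaf_px[id(node)]
            node_px[id(node)] = (x, depth)  # height 0 at the leaf line
            return x
        xl = rec(node.left)
        xr = rec(node.right)
        x = (xl + xr) / 2.0
        node_px[id(node)] = (x, depth * (1.0 - node.height / max_h))
        return x

    rec(tree.root)
    return _DendroGeom(leaf_px, node_px, step)


def _dendro_polylines(tree: MergeTree, geom: _DendroGeom,
                      transpose: bool = False,
                      dx: float = 0.0, dy: float = 0.0) -> list[str]:
    """One 4-point polyline per merge: riser, connector, riser."""
    lines = []
    for node in tree.internal_nodes():
        xl, yl = geom.node_px[id(node.left)]
        xr, yr = geom.node_px[id(node.right)]
        _, y = geom.node_px[id(node)]
        pts = [(xl, yl), (xl, y), (xr, y), (xr, yr)]
        if transpose:
            pts = [(p[1], p[0]) for p in pts]
        coords = " ".join(f"{_F(px + dx)},{_F(py + dy)}" for px, py in pts)
        lines.append(
            f'<polyline points="{coords}" fill="none" stroke="#000000" stroke-width="1"/>'
        )
    return lines


def render_dendrogram(
    tree: MergeTree,
    width: float = 600.0,
    height: float = 400.0,
    orientation: str = "bottom",
    show_labels: bool = True,
    highlight=(),
    label_min_px: float = 4.0,
    margin: float = 10.0,
    label_space: float = 60.0,
) -> str:
    """Draw a dendrogram as an SVG document (returned as text).

    ``orientation="bottom"`` puts leaves along the bottom edge,
    ``"right"`` along the right edge. Leaf labels are drawn only when each
    leaf has at least ``label_min_px`` pixels of room (the limited-display
    mode: shrink the canvas and labels drop out instead of overplotting).
    Labels listed in ``highlight`` are emphasized in red bold.
    """
    if width <= 0 or height <= 0:
        raise ValidationError("canvas width and height must be positive")
    if orientation not in ("bottom", "right"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    leaves = list(tree.leaves())
    n = len(leaves)
    labelled = show_labels
    if orientation == "bottom":
        extent = width - 2 * margin
        depth = height - 2 * margin - (label_space if labelled else 0)
    else:
        extent = height - 2 * margin
        depth = width - 2 * margin - (label_space if labelled else 0)
    geom = _layout(tree, extent, depth)
    if geom.step < label_min_px:
        labelled = False
    highlight = set(highlight)
    parts = [_svg_open(width, height), '<g class="dendrogram">']
    parts += _dendro_polylines(tree, geom, transpose=(orientation == "right"),
                               dx=margin, dy=margin)
    parts.append("</g>")
    if labelled:
        parts.append('<g class="leaf-labels">')
        font = max(4.0, min(12.0, geom.step * 0.8))
        for l in leaves:
            x = geom.leaf_px[id(l)]
            style = ' fill="#b2182b" font-weight="bold"' if l.label in highlight else ""
            if orientation == "bottom":
                px, py = margin + x, margin + depth + font
                parts.append(
                    f'<text x="{_F(px)}" y="{_F(py)}" font-size="{_F(font)}" '
                    f'text-anchor="middle"{style}>{_esc(l.label)}</text>'
                )
            else:
                px, py = margin + depth + 4, margin + x + font / 2
                parts.append(
                    f'<text x="{_F(px)}" y="{_F(py)}" font-size="{_F(font)}"'
                    f'{style}>{_esc(l.label)}</text>'
                )
        parts.append("</g>")
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))


def render_heatmap(
    matrix: pd.DataFrame,
    row_tree: MergeTree,
    col_tree: MergeTree | None = None,
    annotations=None,
    vmin: float | None = None,
    vmax: float | None = None,
    cell: float = 8.0,
    dendro_px: float = 80.0,
    annot_px: float = 10.0,
    margin: float = 10.0,
    symmetric: bool = False,
) -> str:
    """Draw a cluster heat map: matrix cells reordered by the trees' leaf
    orders, the row dendrogram on the left, an optional column dendrogram on
    top, and an optional categorical annotation strip between the row
    dendrogram and the cells.

    ``symmetric=True`` renders a square matrix (e.g. a distance matrix)
    ordered by the row tree on both axes. ``vmin``/``vmax`` set the diverging
    color limits (default: symmetric around 0 if the data straddle 0, else
    the data range).
    """
    rows = leaf_order(row_tree)
    missing = [r for r in rows if r not in matrix.index]
    if missing:
        raise ValidationError(f"row labels missing from matrix: {missing[:5]}")
    if symmetric:
        cols = rows
        col_tree = None
    elif col_tree is not None:
        cols = leaf_order(col_tree)
        missing = [c for c in cols if c not in matrix.columns]
        if missing:
            raise ValidationError(f"column labels missing from matrix: {missing[:5]}")
    else:
        cols = [str(c) for c in matrix.columns]
    data = matrix.loc[rows, cols].to_numpy(dtype=float)
    if vmin is None or vmax is None:
        lo, hi = float(np.nanmin(data)), float(np.nanmax(data))
        if lo < 0 < hi:
            m = max(abs(lo), abs(hi))
            lo, hi = -m, m
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        vmin = lo if vmin is None else vmin
        vmax = hi if vmax is None else vmax

    n_r, n_c = len(rows), len(cols)
    x_cells = margin + dendro_px + (annot_px if annotations is not None else 0)
    y_cells = margin + (dendro_px if col_tree is not None else 0)
    width = x_cells + n_c * cell + margin
    height = y_cells + n_r * cell + margin
    parts = [_svg_open(width, height)]

    # row dendrogram, leaves pointing right toward the matrix
    geom_r = _layout(row_tree, n_r * cell, dendro_px)
    parts.append('<g class="row-dendrogram">')
    parts += _dendro_polylines(row_tree, geom_r, transpose=True,
                               dx=margin, dy=y_cells)
    parts.append("</g>")

    if col_tree is not None:
        geom_c = _layout(col_tree, n_c * cell, dendro_px)
        parts.append('<g class="col-dendrogram">')
        parts += _dendro_polylines(col_tree, geom_c, transpose=False,
                                   dx=x_cells, dy=margin)
        parts.append("</g>")

    if annotations is not None:
        ann = {str(k): str(v) for k, v in
               (annotations.items() if hasattr(annotations, "items")
                else zip(rows, annotations))}
        missing = [r for r in rows if r not in ann]
        if missing:
            raise ValidationError(f"annotation missing for rows: {missing[:5]}")
        cats = sorted(set(ann[r] for r in rows))
        fill = {c: ANNOTATION_PALETTE[i % len(ANNOTATION_PALETTE)]
                for i, c in enumerate(cats)}
        parts.append('<g class="row-annotation">')
        for i, r in enumerate(rows):
            parts.append(
                f'<rect x="{_F(margin + dendro_px)}" y="{_F(y_cells + i * cell)}" '
                f'width="{_F(annot_px)}" height="{_F(cell)}" '
                f'fill="{fill[ann[r]]}"><title>{_esc(ann[r])}</title></rect>'
            )
        parts.append("</g>")

    parts.append('<g class="cells">')
    for i in range(n_r):
        for j in range(n_c):
            parts.append(
                f'<rect x="{_F(x_cells + j * cell)}" y="{_F(y_cells + i * cell)}" '
                f'width="{_F(cell)}" height="{_F(cell)}" '
                f'fill="{diverging_color(data[i, j], vmin, vmax)}"/>'
            )
    parts.append("</g>")
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
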