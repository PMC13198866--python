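"""Static rendering of the alignment graph.

Sequence A runs down the vertical axis and sequence B along the
horizontal axis, origin top-left, matching the dynamic-programming
matrix convention: a match/mismatch is a diagonal line, an indel a
vertical or horizontal line.  Edge opacity encodes the exact support
fraction of each edge, safety windows are shaded green, the optimal path
is stroked blue and an optional user-selected path orange.

Geometry is computed once as a backend-neutral primitive list; the SVG
backend writes it verbatim (byte-deterministic), and PNG/JPEG are
rasterised from the same primitives with matplotlib.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

from .core_dag import (
    DIAGONAL,
    HORIZONTAL,
    VERTICAL,
    AlignmentDag,
    DagEdge,
    D_STATE,
    I_STATE,
    M_STATE,
    align_optimal,
)
from .safety import SafetyResult

__all__ = ["RenderSpec", "render_alignment_graph", "path_from_moves"]

_EDGE_COLOR = "#555555"
_WINDOW_COLOR = "#2e8b57"
_OPTIMAL_COLOR = "#1f6fd0"
_SELECTED_COLOR = "#e88a1a"


@dataclass
class RenderSpec:
    """Layer toggles and geometry for a render."""

    show_grid: bool = True
    show_supports: bool = True
    show_windows: bool = True
    show_optimal: bool = True
    selected_path: Sequence[DagEdge] | None = None
    fmt: str = "SVG"  # SVG | PNG | JPEG
    cell: int = 28
    margin: int = 52
    dpi: int = 96

    def __post_init__(self) -> None:
        if self.fmt.upper() not in ("SVG", "PNG", "JPEG"):
            raise ValueError(f"unsupported image format {self.fmt!r}")


def _validate_selected(dag: AlignmentDag, path: Sequence[DagEdge]) -> None:
    if not path:
        raise ValueError("selected path is empty")
    if path[0].frm != dag.source:
        raise ValueError("selected path does not start at the source")
    for prev, nxt in zip(path, path[1:]):
        if prev.to != nxt.frm:
            raise ValueError("selected path is not contiguous")
    for e in path:
        if e not in dag.edge_set:
            raise ValueError(f"selected path uses edge {e} absent from the graph")
    m, n = dag.shape
    if path[-1].to[:2] != (m, n):
        raise ValueError("selected path does not reach the sink")


def _geometry(dag: AlignmentDag, result: SafetyResult, spec: RenderSpec):
    """Backend-neutral draw list: ('rect'|'line'|'poly'|'text', ...)."""
    cell, margin = spec.cell, spec.margin
    m, n = dag.shape

    def node(i: int, j: int) -> tuple[int, int]:
        return margin + j * cell, margin + i * cell

    width = 2 * margin + n * cell
    height = 2 * margin + m * cell
    prims: list[tuple] = []

    if spec.show_windows:
        for w in result.windows:
            (a0, a1), (b0, b1) = w.a_interval, w.b_interval
            x, y = node(a0, b0)
            prims.append(
                ("rect", x, y, max((b1 - b0) * cell, 3), max((a1 - a0) * cell, 3),
                 _WINDOW_COLOR, 0.25)
            )

    if spec.show_grid:
        track = result.edge_fractions if spec.show_supports else None
        for e in dag.edges:
            x1, y1 = node(e.frm[0], e.frm[1])
            x2, y2 = node(e.to[0], e.to[1])
            opacity = 1.0
            if track is not None:
                frac = track.get(e)
                if frac is not None:
                    opacity = max(
                        round(frac.numerator / frac.denominator, 4), 0.05
                    )
            prims.append(("line", x1, y1, x2, y2, e.kind, _EDGE_COLOR, opacity))

    def poly_points(path: Sequence[DagEdge]) -> list[tuple[int, int]]:
        pts = [node(path[0].frm[0], path[0].frm[1])]
        pts.extend(node(e.to[0], e.to[1]) for e in path)
        return pts

    if spec.show_optimal:
        _, opt_path = align_optimal(dag.seq_a, dag.seq_b, dag.params)
        if opt_path:
            prims.append(("poly", poly_points(opt_path), _OPTIMAL_COLOR))
    if spec.selected_path is not None:
        _validate_selected(dag, spec.selected_path)
        prims.append(("poly", poly_points(spec.selected_path), _SELECTED_COLOR))

    for k, ch in enumerate(dag.seq_a):
        x, y = node(k, 0)
        prims.append(("text", margin - 28, y + cell // 2 + 4, f"{ch}{k + 1}"))
    for k, ch in enumerate(dag.seq_b):
        x, y = node(0, k)
        prims.append(("text", x + cell // 2 - 6, margin - 16, f"{ch}{k + 1}"))

    return width, height, prims


def _render_svg(width: int, height: int, prims: list[tuple]) -> bytes:
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect x="0" y="0" width="{width}" height="{height}" fill="#ffffff"/>',
    ]
    for p in prims:
        if p[0] == "rect":
            _, x, y, w, h, color, opacity = p
            out.append(
                f'<rect class="window" x="{x}" y="{y}" width="{w}" height="{h}" '
                f'fill="{color}" fill-opacity="{opacity}"/>'
            )
        elif p[0] == "line":
            _, x1, y1, x2, y2, kind, color, opacity = p
            out.append(
                f'<line class="{kind}" x1="{x1}" y1="{y1}" x2="{x2}" y2="{y2}" '
                f'stroke="{color}" stroke-width="2" stroke-opacity="{opacity}"/>'
            )
        elif p[0] == "poly":
            _, pts, color = p
            points = " ".join(f"{x},{y}" for x, y in pts)
            out.append(
                f'<polyline class="path" points="{points}" fill="none" '
                f'stroke="{color}" stroke-width="3.5" stroke-opacity="0.9"/>'
            )
        elif p[0] == "text":
            _, x, y, s = p
            out.append(
                f'<text class="label" x="{x}" y="{y}" '
                f'font-family="monospace" font-size="12">{s}</text>'
            )
    out.append("</svg>")
    return ("\n".join(out) + "\n").encode("utf-8")


def _render_raster(width: int, height: int, prims: list[tuple], fmt: str, dpi: int) -> bytes:
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib.figure import Figure
    from matplotlib.patches import Rectangle

    fig = Figure(figsize=(width / 72, height / 72), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # origin top-left
    ax.axis("off")
    for p in prims:
        if p[0] == "rect":
            _, x, y, w, h, color, opacity = p
            ax.add_patch(Rectangle((x, y), w, h, facecolor=color, alpha=opacity, lw=0))
        elif p[0] == "line":
            _, x1, y1, x2, y2, _kind, color, opacity = p
            ax.plot([x1, x2], [y1, y2], color=color, alpha=float(opacity), lw=1.5)
        elif p[0] == "poly":
            _, pts, color = p
            ax.plot([x for x, _ in pts], [y for _, y in pts], color=color, lw=2.5, alpha=0.9)
        elif p[0] == "text":
            _, x, y, s = p
            ax.text(x, y, s, fontsize=8, family="monospace")
    buf = io.BytesIO()
    fig.savefig(buf, format="jpeg" if fmt == "JPEG" else "png", dpi=dpi)
    return buf.getvalue()


def render_alignment_graph(
    dag: AlignmentDag, result: SafetyResult, spec: RenderSpec | None = None
) -> bytes:
    """Render the alignment graph; returns image bytes in ``spec.fmt``."""
    spec = spec if spec is not None else RenderSpec()
    width, height, prims = _geometry(dag, result, spec)
    fmt = spec.fmt.upper()
    if fmt == "SVG":
        return _render_svg(width, height, prims)
    return _render_raster(width, height, prims, fmt, spec.dpi)


_MOVE_TO_STATE = {"D": M_STATE, "V": D_STATE, "H": I_STATE}
_MOVE_TO_KIND = {"D": DIAGONAL, "V": VERTICAL, "H": HORIZONTAL}


def path_from_moves(dag: AlignmentDag, moves: str) -> tuple[DagEdge, ...]:
    """Resolve a move string (D/V/H per step) into an edge path through
    the graph, usable as ``RenderSpec.selected_path``."""
    v = dag.source
    path: list[DagEdge] = []
    for k, mv in enumerate(moves):
        kind = _MOVE_TO_KIND.get(mv)
        if kind is None:
            raise ValueError(f"illegal move character {mv!r} at position {k + 1}")
        edge = None
        for e in dag.out_edges.get(v, ()):
            if e.kind == kind:
                edge = e
                break
        if edge is None:
            raise ValueError(
                f"illegal move at position {k + 1}: no {kind} edge from vertex {v}"
            )
        path.append(edge)
        v = edge.to
    m, n = dag.shape
    if v[:2] != (m, n):
        raise ValueError("move string stops before reaching the sink")
    return tuple(path)
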