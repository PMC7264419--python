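"""The four visualizations as explicit node/edge graphs, plus renderers.

Builders produce a :class:`DiagramGraph` for the frequency net, the
double-tree, the two simple trees and the 2×2 table, in probability,
frequency or simultaneous ("both") mode.  The net is the richest of the
four: nine nodes (a central total, four margins, four cells) and sixteen
branches — four marginal (solid, on the axes), four joint (dashed,
diagonal) and eight conditional (along the border).  Both simple trees and
both 2×2 tables are embedded inside it.

Renderers emit a deterministic monospaced text sketch and an SVG 1.1
document.  The double-tree's two crossing middle branches reproduce, by
default, the label-placement ambiguity known from printed double-trees;
the ``disambiguated`` layout moves the upward labels apart.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple, Union

from ._format import format_count, format_percent
from .quantities import QuantityId
from .situation import (
    CompletedSituation,
    FrequencyTable,
    to_frequencies,
)

__all__ = [
    "DiagramNode",
    "DiagramEdge",
    "DiagramGraph",
    "SvgLayout",
    "build_net",
    "build_double_tree",
    "build_tree",
    "build_two_by_two",
    "render_text",
    "render_svg",
]


@dataclass
class DiagramNode:
    id: str
    role: str  # 'center' | 'margin' | 'cell' | 'header'
    pos: Tuple[float, float]  # layout coordinates, y grows upward
    title: Optional[str] = None  # event name, for headers and sketches
    freq_label: Optional[str] = None
    prob_label: Optional[str] = None
    freq_value: Optional[Union[int, Fraction]] = None
    prob_value: Optional[Fraction] = None
    quantity: Optional[QuantityId] = None


@dataclass
class DiagramEdge:
    id: str
    ends: Tuple[str, str]
    role: str  # 'marginal' | 'conditional' | 'joint'
    style: str  # 'solid' | 'dashed'
    quantity: Optional[QuantityId] = None
    value: Optional[Fraction] = None
    label: Optional[str] = None
    secondary_quantity: Optional[QuantityId] = None
    secondary_value: Optional[Fraction] = None
    secondary_label: Optional[str] = None
    crossing: bool = False


@dataclass
class DiagramGraph:
    kind: str  # 'net' | 'double_tree' | 'tree_A_first' | 'tree_B_first' | 'two_by_two'
    mode: str  # 'prob' | 'freq' | 'both'
    nodes: List[DiagramNode] = field(default_factory=list)
    edges: List[DiagramEdge] = field(default_factory=list)
    layout: str = "default"

    def node(self, node_id: str) -> DiagramNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def edge(self, edge_id: str) -> DiagramEdge:
        for e in self.edges:
            if e.id == edge_id:
                return e
        raise KeyError(edge_id)


_MARGINS = {
    "A": QuantityId.A,
    "notA": QuantityId.NOT_A,
    "B": QuantityId.B,
    "notB": QuantityId.NOT_B,
}
_CELLS = {
    "A&B": QuantityId.A_AND_B,
    "A&notB": QuantityId.A_AND_NOT_B,
    "notA&B": QuantityId.NOT_A_AND_B,
    "notA&notB": QuantityId.NOT_A_AND_NOT_B,
}
_CONDITIONALS = {
    ("A", "B"): QuantityId.B_GIVEN_A,      # from margin A toward cell A&B
    ("A", "notB"): QuantityId.NOT_B_GIVEN_A,
    ("notA", "B"): QuantityId.B_GIVEN_NOT_A,
    ("notA", "notB"): QuantityId.NOT_B_GIVEN_NOT_A,
    ("B", "A"): QuantityId.A_GIVEN_B,      # from margin B toward cell A&B
    ("B", "notA"): QuantityId.NOT_A_GIVEN_B,
    ("notB", "A"): QuantityId.A_GIVEN_NOT_B,
    ("notB", "notA"): QuantityId.NOT_A_GIVEN_NOT_B,
}


def _resolve_counts(
    situation: CompletedSituation, N: Optional[int], mode: str
) -> Optional[FrequencyTable]:
    if mode not in ("prob", "freq", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "prob":
        return None
    n = N if N is not None else situation.population_size
    if n is None:
        raise ValueError(f"mode {mode!r} requires a population size N")
    return to_frequencies(situation, n, policy="exact")


def _node_labels(
    node: DiagramNode,
    counts: Optional[FrequencyTable],
    mode: str,
    q: Optional[QuantityId],
) -> None:
    if counts is not None and q is not None:
        node.freq_value = counts.count(q)
        node.freq_label = format_count(node.freq_value)


def _edge_prob(
    edge: DiagramEdge, situation: CompletedSituation, mode: str, decimals: int
) -> None:
    if mode == "freq" or edge.quantity is None:
        return
    v = situation.value(edge.quantity)
    edge.value = v
    edge.label = None if v is None else format_percent(v, decimals)
    if edge.secondary_quantity is not None:
        sv = situation.value(edge.secondary_quantity)
        edge.secondary_value = sv
        edge.secondary_label = None if sv is None else format_percent(sv, decimals)


def build_net(
    situation: CompletedSituation,
    N: Optional[int] = None,
    mode: str = "prob",
    decimals: int = 1,
) -> DiagramGraph:
    """Nine nodes, sixteen branches; no crossings, no doubled node."""
    counts = _resolve_counts(situation, N, mode)
    g = DiagramGraph("net", mode)
    ev = situation.event_pair
    positions = {
        "total": (0.0, 0.0),
        "A": (0.0, 2.0),
        "notA": (0.0, -2.0),
        "B": (-2.0, 0.0),
        "notB": (2.0, 0.0),
        "A&B": (-2.0, 2.0),
        "A&notB": (2.0, 2.0),
        "notA&B": (-2.0, -2.0),
        "notA&notB": (2.0, -2.0),
    }
    g.nodes.append(
        DiagramNode("total", "center", positions["total"], title="total",
                    quantity=QuantityId.TOTAL)
    )
    for tok, q in _MARGINS.items():
        g.nodes.append(
            DiagramNode(tok, "margin", positions[tok], title=ev.label(tok),
                        quantity=q)
        )
    for cid, q in _CELLS.items():
        g.nodes.append(
            DiagramNode(cid, "cell", positions[cid], title=cid, quantity=q)
        )
    for n in g.nodes:
        _node_labels(n, counts, mode, n.quantity)

    for tok, q in _MARGINS.items():
        g.edges.append(
            DiagramEdge(f"edge:{q}", ("total", tok), "marginal", "solid",
                        quantity=q)
        )
    for cid, q in _CELLS.items():
        g.edges.append(
            DiagramEdge(f"edge:{q}", ("total", cid), "joint", "dashed",
                        quantity=q)
        )
    for (margin_tok, target_tok), q in _CONDITIONALS.items():
        cell_id = next(
            cid for cid in _CELLS
            if set(cid.split("&")) == {margin_tok, target_tok}
        )
        g.edges.append(
            DiagramEdge(f"edge:{q}", (margin_tok, cell_id), "conditional",
                        "solid", quantity=q)
        )
    for e in g.edges:
        _edge_prob(e, situation, mode, decimals)
    return g


def build_double_tree(
    situation: CompletedSituation,
    N: Optional[int] = None,
    mode: str = "prob",
    decimals: int = 1,
    layout: str = "default",
) -> DiagramGraph:
    """Six nodes; the four middle branches carry both reading directions.

    The downward labels condition on the first event (P(B|A)-style), the
    upward labels on the second (P(A|B)-style).  The branches A↔¬B and
    ¬A↔B cross; with ``layout='disambiguated'`` the SVG renderer pulls
    their upward labels apart instead of stacking them at the crossing.
    """
    if layout not in ("default", "disambiguated"):
        raise ValueError(f"unknown layout {layout!r}")
    counts = _resolve_counts(situation, N, mode)
    g = DiagramGraph("double_tree", mode, layout=layout)
    ev = situation.event_pair
    positions = {
        "total_top": (0.0, 3.0),
        "A": (-1.5, 2.0),
        "notA": (1.5, 2.0),
        "B": (-1.5, 1.0),
        "notB": (1.5, 1.0),
        "total_bottom": (0.0, 0.0),
    }
    g.nodes.append(DiagramNode("total_top", "center", positions["total_top"],
                               title="total", quantity=QuantityId.TOTAL))
    for tok in ("A", "notA", "B", "notB"):
        g.nodes.append(DiagramNode(tok, "margin", positions[tok],
                                   title=ev.label(tok), quantity=_MARGINS[tok]))
    g.nodes.append(DiagramNode("total_bottom", "center",
                               positions["total_bottom"], title="total",
                               quantity=QuantityId.TOTAL))
    for n in g.nodes:
        _node_labels(n, counts, mode, n.quantity)

    g.edges.append(DiagramEdge("edge:P(A)", ("total_top", "A"), "marginal",
                               "solid", quantity=QuantityId.A))
    g.edges.append(DiagramEdge("edge:P(notA)", ("total_top", "notA"),
                               "marginal", "solid", quantity=QuantityId.NOT_A))
    middle = [
        ("A", "B", QuantityId.B_GIVEN_A, QuantityId.A_GIVEN_B, False),
        ("A", "notB", QuantityId.NOT_B_GIVEN_A, QuantityId.A_GIVEN_NOT_B, True),
        ("notA", "B", QuantityId.B_GIVEN_NOT_A, QuantityId.NOT_A_GIVEN_B, True),
        ("notA", "notB", QuantityId.NOT_B_GIVEN_NOT_A,
         QuantityId.NOT_A_GIVEN_NOT_B, False),
    ]
    for top, bottom, down_q, up_q, crossing in middle:
        g.edges.append(
            DiagramEdge(f"edge:{down_q}", (top, bottom), "conditional",
                        "solid", quantity=down_q, secondary_quantity=up_q,
                        crossing=crossing)
        )
    g.edges.append(DiagramEdge("edge:P(B)", ("B", "total_bottom"), "marginal",
                               "solid", quantity=QuantityId.B))
    g.edges.append(DiagramEdge("edge:P(notB)", ("notB", "total_bottom"),
                               "marginal", "solid", quantity=QuantityId.NOT_B))
    for e in g.edges:
        _edge_prob(e, situation, mode, decimals)
    return g


def build_tree(
    situation: CompletedSituation,
    N: Optional[int] = None,
    mode: str = "prob",
    orientation: str = "A_first",
    decimals: int = 1,
) -> DiagramGraph:
    """A classic two-level tree; only 4 of the 8 conditionals appear."""
    if orientation not in ("A_first", "B_first"):
        raise ValueError(f"unknown orientation {orientation!r}")
    counts = _resolve_counts(situation, N, mode)
    g = DiagramGraph(f"tree_{orientation}", mode)
    ev = situation.event_pair
    first = ("A", "notA") if orientation == "A_first" else ("B", "notB")
    second = ("B", "notB") if orientation == "A_first" else ("A", "notA")

    g.nodes.append(DiagramNode("total", "center", (0.0, 2.0), title="total",
                               quantity=QuantityId.TOTAL))
    xs = (-1.5, 1.5)
    for tok, x in zip(first, xs):
        g.nodes.append(DiagramNode(tok, "margin", (x, 1.0),
                                   title=ev.label(tok), quantity=_MARGINS[tok]))
    leaf_x = (-2.25, -0.75, 0.75, 2.25)
    i = 0
    for tok in first:
        for sec in second:
            cell_id = next(
                cid for cid in _CELLS if set(cid.split("&")) == {tok, sec}
            )
            g.nodes.append(
                DiagramNode(cell_id, "cell", (leaf_x[i], 0.0), title=cell_id,
                            quantity=_CELLS[cell_id])
            )
            i += 1
    for n in g.nodes:
        _node_labels(n, counts, mode, n.quantity)

    for tok in first:
        q = _MARGINS[tok]
        g.edges.append(DiagramEdge(f"edge:{q}", ("total", tok), "marginal",
                                   "solid", quantity=q))
    for tok in first:
        for sec in second:
            q = _CONDITIONALS[(tok, sec)]
            cell_id = next(
                cid for cid in _CELLS if set(cid.split("&")) == {tok, sec}
            )
            g.edges.append(DiagramEdge(f"edge:{q}", (tok, cell_id),
                                       "conditional", "solid", quantity=q))
    for e in g.edges:
        _edge_prob(e, situation, mode, decimals)
    return g


def build_two_by_two(
    situation: CompletedSituation,
    N: Optional[int] = None,
    mode: str = "prob",
    decimals: int = 1,
) -> DiagramGraph:
    """A 4×4 node grid: headers, four cells, four margins and the total.

    In probability mode the cells carry joints and the margins marginals —
    no conditional appears anywhere, which is exactly the 2×2 table's
    structural limitation.  In frequency mode all nine counts appear.
    """
    counts = _resolve_counts(situation, N, mode)
    g = DiagramGraph("two_by_two", mode)
    ev = situation.event_pair

    def pos(row: int, col: int) -> Tuple[float, float]:
        return (float(col), float(-row))

    g.nodes.append(DiagramNode("corner", "header", pos(0, 0), title=""))
    g.nodes.append(DiagramNode("hdr:B", "header", pos(0, 1), title=ev.label("B")))
    g.nodes.append(DiagramNode("hdr:notB", "header", pos(0, 2),
                               title=ev.label("notB")))
    g.nodes.append(DiagramNode("hdr:sum_row", "header", pos(0, 3), title="total"))
    grid = [
        ("A", 1, [("A&B", 1), ("A&notB", 2)]),
        ("notA", 2, [("notA&B", 1), ("notA&notB", 2)]),
    ]
    for tok, row, cells in grid:
        g.nodes.append(DiagramNode(f"hdr:{tok}", "header", pos(row, 0),
                                   title=ev.label(tok)))
        for cid, col in cells:
            g.nodes.append(DiagramNode(cid, "cell", pos(row, col), title=cid,
                                       quantity=_CELLS[cid]))
        g.nodes.append(DiagramNode(tok, "margin", pos(row, 3),
                                   title=ev.label(tok), quantity=_MARGINS[tok]))
    g.nodes.append(DiagramNode("hdr:sum_col", "header", pos(3, 0), title="total"))
    g.nodes.append(DiagramNode("B", "margin", pos(3, 1), title=ev.label("B"),
                               quantity=QuantityId.B))
    g.nodes.append(DiagramNode("notB", "margin", pos(3, 2),
                               title=ev.label("notB"), quantity=QuantityId.NOT_B))
    g.nodes.append(DiagramNode("total", "center", pos(3, 3), title="total",
                               quantity=QuantityId.TOTAL))

    for n in g.nodes:
        if n.quantity is None:
            continue
        _node_labels(n, counts, mode, n.quantity)
        if mode in ("prob", "both"):
            v = (Fraction(1) if n.quantity is QuantityId.TOTAL
                 else situation.value(n.quantity))
            n.prob_value = v
            n.prob_label = format_percent(v, decimals)
    return g


# ---------------------------------------------------------------------------
# text rendering

def _node_text(node: DiagramNode) -> str:
    parts = [p for p in (node.freq_label, node.prob_label) if p]
    if parts:
        return " | ".join(parts)
    return node.title if node.title is not None else node.id


def render_text(graph: DiagramGraph) -> str:
    """Deterministic monospaced sketch: node boxes row by row, then the
    branch list.  Crossing double-tree branches get a distinct ``--x--``
    glyph."""
    lines = [f"{graph.kind} ({graph.mode})"]
    rows: Dict[float, List[DiagramNode]] = {}
    for n in graph.nodes:
        rows.setdefault(-n.pos[1], []).append(n)
    grid_rows = []
    for y in sorted(rows):
        row = sorted(rows[y], key=lambda n: n.pos[0])
        grid_rows.append([f"[{_node_text(n)}]" for n in row])
    ncols = max(len(r) for r in grid_rows)
    widths = [
        max((len(r[c]) for r in grid_rows if len(r) == ncols), default=0)
        for c in range(ncols)
    ]
    for r in grid_rows:
        if len(r) == ncols:
            lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip())
        else:
            lines.append("  ".join(r))
    if graph.edges:
        lines.append("branches:")
        for e in graph.edges:
            glyph = "--x--" if e.crossing else "-----"
            desc = f"  {e.ends[0]} {glyph} {e.ends[1]}  [{e.role}"
            if e.label:
                desc += f" {e.quantity} = {e.label}"
            if e.secondary_label:
                desc += f"; upward {e.secondary_quantity} = {e.secondary_label}"
            desc += "]"
            lines.append(desc)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SVG rendering

@dataclass
class SvgLayout:
    """Geometry knobs for the SVG renderer."""

    scale: float = 110.0
    margin: float = 70.0
    node_rx: float = 30.0
    node_ry: float = 16.0
    font_size: float = 12.0
    min_label_separation: float = 40.0


def _coords(graph: DiagramGraph, layout: SvgLayout) -> Dict[str, Tuple[float, float]]:
    xs = [n.pos[0] for n in graph.nodes]
    ys = [n.pos[1] for n in graph.nodes]
    x0, y1 = min(xs), max(ys)
    return {
        n.id: (
            layout.margin + (n.pos[0] - x0) * layout.scale,
            layout.margin + (y1 - n.pos[1]) * layout.scale,
        )
        for n in graph.nodes
    }


def render_svg(graph: DiagramGraph, layout: Optional[SvgLayout] = None) -> str:
    """Render as a self-contained SVG 1.1 document (deterministic text)."""
    if graph.kind not in (
        "net", "double_tree", "tree_A_first", "tree_B_first", "two_by_two"
    ):
        raise ValueError(f"unknown diagram kind {graph.kind!r}")
    layout = layout or SvgLayout()
    pts = _coords(graph, layout)
    width = max(x for x, _ in pts.values()) + layout.margin
    height = max(y for _, y in pts.values()) + layout.margin

    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": f"{width:g}",
        "height": f"{height:g}",
        "font-family": "sans-serif",
        "font-size": f"{layout.font_size:g}",
    })

    for e in graph.edges:
        (x1, y1), (x2, y2) = pts[e.ends[0]], pts[e.ends[1]]
        attrs = {
            "id": e.id,
            "x1": f"{x1:g}", "y1": f"{y1:g}",
            "x2": f"{x2:g}", "y2": f"{y2:g}",
            "stroke": "black",
            "class": f"edge {e.role}",
        }
        if e.style == "dashed":
            attrs["stroke-dasharray"] = "6,4"
        ET.SubElement(svg, "line", attrs)

        def _anchor(t: float) -> Tuple[float, float]:
            return (x1 + t * (x2 - x1), y1 + t * (y2 - y1))

        if e.label:
            lx, ly = _anchor(0.5)
            label = ET.SubElement(svg, "text", {
                "id": f"label:{e.id}",
                "x": f"{lx:g}", "y": f"{ly - 4:g}",
                "text-anchor": "middle",
            })
            label.text = e.label
        if e.secondary_label:
            # default: both upward labels sit at the edge midpoint — for the
            # two crossing branches those midpoints coincide, reproducing the
            # printed double-tree's hazard; 'disambiguated' pulls them toward
            # their lower nodes.
            t = 0.8 if (graph.layout == "disambiguated" and e.crossing) else 0.5
            lx, ly = _anchor(t)
            label = ET.SubElement(svg, "text", {
                "id": f"label2:{e.id}",
                "x": f"{lx:g}", "y": f"{ly + layout.font_size:g}",
                "text-anchor": "middle",
            })
            label.text = e.secondary_label

    for n in graph.nodes:
        x, y = pts[n.id]
        shape = "rect" if graph.kind == "two_by_two" else "ellipse"
        if shape == "ellipse":
            ET.SubElement(svg, "ellipse", {
                "id": f"node:{n.id}",
                "cx": f"{x:g}", "cy": f"{y:g}",
                "rx": f"{layout.node_rx:g}", "ry": f"{layout.node_ry:g}",
                "fill": "white", "stroke": "black",
            })
        else:
            ET.SubElement(svg, "rect", {
                "id": f"node:{n.id}",
                "x": f"{x - layout.node_rx:g}", "y": f"{y - layout.node_ry:g}",
                "width": f"{2 * layout.node_rx:g}",
                "height": f"{2 * layout.node_ry:g}",
                "fill": "white",
                "stroke": "black" if n.role != "header" else "none",
            })
        text = _node_text(n)
        if text:
            el = ET.SubElement(svg, "text", {
                "id": f"text:{n.id}",
                "x": f"{x:g}", "y": f"{y + layout.font_size / 3:g}",
                "text-anchor": "middle",
            })
            el.text = text

    body = ET.tostring(svg, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"
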