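"""Structure, label consistency and rendering of the four diagrams."""

import xml.etree.ElementTree as ET
from fractions import Fraction as F

import pytest

from freqnet.diagrams import (
    SvgLayout,
    build_double_tree,
    build_net,
    build_tree,
    build_two_by_two,
    render_svg,
    render_text,
)
from freqnet.quantities import QuantityId as Q
from freqnet.situation import CellDistribution, complete_from_cells, to_frequencies

SVG = "{http://www.w3.org/2000/svg}"

UNIFORM = complete_from_cells(
    CellDistribution(F(1, 4), F(1, 4), F(1, 4), F(1, 4))
)


# ---------------------------------------------------------------------------
# net

def test_net_structure(mam_situation):
    g = build_net(mam_situation, N=10_000, mode="both")
    assert len(g.nodes) == 9 and len(g.edges) == 16
    roles = [n.role for n in g.nodes]
    assert roles.count("center") == 1
    assert roles.count("margin") == 4 and roles.count("cell") == 4
    by_role = {"marginal": 0, "joint": 0, "conditional": 0}
    for e in g.edges:
        by_role[e.role] += 1
        assert (e.style == "dashed") == (e.role == "joint")
        assert not e.crossing
    assert by_role == {"marginal": 4, "joint": 4, "conditional": 8}


def test_net_both_mode_carries_counts_and_probabilities(mam_situation):
    g = build_net(mam_situation, N=10_000, mode="both")
    assert g.node("total").freq_label == "10,000"
    e = g.edge("edge:P(A&B)")
    assert e.value == F("0.016") and e.label == "1.6%"
    assert g.node("A&B").freq_value == 160


def test_net_label_consistency(mam_situation):
    """Every labeled value equals the derived quantity, exactly."""
    g = build_net(mam_situation, N=10_000, mode="both")
    counts = to_frequencies(mam_situation, 10_000, policy="exact")
    for e in g.edges:
        assert e.value == mam_situation.value(e.quantity)
    for n in g.nodes:
        assert n.freq_value == counts.count(n.quantity)


def test_net_mode_separation(mam_situation):
    prob = build_net(mam_situation, mode="prob")
    assert all(n.freq_label is None for n in prob.nodes)
    assert all(e.label is not None for e in prob.edges)
    freq = build_net(mam_situation, N=10_000, mode="freq")
    assert all(e.label is None for e in freq.edges)
    assert all(n.freq_label is not None for n in freq.nodes)


def test_net_uniform_symmetry():
    g = build_net(UNIFORM, mode="prob")
    assert {e.value for e in g.edges if e.role == "joint"} == {F(1, 4)}
    assert {e.value for e in g.edges if e.role == "conditional"} == {F(1, 2)}


def test_net_requires_population_for_frequency_modes():
    # UNIFORM has no stored population size
    with pytest.raises(ValueError, match="population"):
        build_net(UNIFORM, mode="freq")


def test_undefined_conditionals_leave_branches_unlabeled():
    s = complete_from_cells(CellDistribution(F(1), F(0), F(0), F(0)))
    g = build_net(s, mode="prob")
    unlabeled = {str(e.quantity) for e in g.edges if e.label is None}
    assert "P(A|notB)" in unlabeled and "P(B|notA)" in unlabeled


# ---------------------------------------------------------------------------
# embeddings (the net contains both trees and both 2x2 tables)

def test_net_contains_both_trees_conditionals(mam_situation):
    net = build_net(mam_situation, N=10_000, mode="both")
    net_labels = {(e.quantity, e.value) for e in net.edges}
    for orientation in ("A_first", "B_first"):
        tree = build_tree(mam_situation, N=10_000, mode="both",
                          orientation=orientation)
        assert {(e.quantity, e.value) for e in tree.edges} <= net_labels


def test_net_corner_nodes_are_the_frequency_table(mam_situation):
    net = build_net(mam_situation, N=10_000, mode="freq")
    table = to_frequencies(mam_situation, 10_000, policy="exact")
    corners = {n.quantity: n.freq_value for n in net.nodes if n.role == "cell"}
    assert corners == {
        Q.A_AND_B: table.n_ab, Q.A_AND_NOT_B: table.n_a_nb,
        Q.NOT_A_AND_B: table.n_na_b, Q.NOT_A_AND_NOT_B: table.n_na_nb,
    }
    margins = {n.quantity: n.freq_value for n in net.nodes if n.role == "margin"}
    assert margins[Q.B] == table.n_b and margins[Q.NOT_A] == table.n_na


def test_net_joint_branches_are_the_probability_table(mam_situation):
    net = build_net(mam_situation, mode="prob")
    tab = build_two_by_two(mam_situation, mode="prob")
    net_joints = {e.quantity: e.value for e in net.edges if e.role == "joint"}
    tab_cells = {n.quantity: n.prob_value for n in tab.nodes if n.role == "cell"}
    assert net_joints == tab_cells


# ---------------------------------------------------------------------------
# double-tree

def test_double_tree_structure(mam_situation):
    g = build_double_tree(mam_situation, N=10_000, mode="freq")
    assert len(g.nodes) == 6
    totals = [n for n in g.nodes if n.role == "center"]
    assert len(totals) == 2 and {n.freq_label for n in totals} == {"10,000"}
    middle = [e for e in g.edges if e.role == "conditional"]
    assert len(middle) == 4
    assert all(e.secondary_quantity is not None for e in middle)
    assert sum(e.crossing for e in middle) == 2


def test_double_tree_crossing_upward_labels(mam_situation):
    g = build_double_tree(mam_situation, mode="prob")
    upward = {str(e.secondary_quantity): e.secondary_value
              for e in g.edges if e.crossing}
    assert upward["P(notA|B)"] == F(49, 57)    # displays as 86%
    assert upward["P(A|notB)"] == F(2, 443)    # displays as 0.5%


def test_double_tree_frequency_node_sequence(mam_situation):
    g = build_double_tree(mam_situation, N=10_000, mode="freq")
    by_level = {}
    for n in g.nodes:
        by_level.setdefault(n.pos[1], []).append(n.freq_value)
    assert by_level[3.0] == [10_000]
    assert sorted(by_level[2.0]) == [200, 9800]
    assert sorted(by_level[1.0]) == [1140, 8860]
    assert by_level[0.0] == [10_000]


# ---------------------------------------------------------------------------
# trees

@pytest.mark.parametrize("orientation,first_margins", [
    ("A_first", {Q.A, Q.NOT_A}),
    ("B_first", {Q.B, Q.NOT_B}),
])
def test_tree_structure(mam_situation, orientation, first_margins):
    g = build_tree(mam_situation, N=10_000, mode="both",
                   orientation=orientation)
    assert len(g.nodes) == 7 and len(g.edges) == 6
    conds = [e for e in g.edges if e.role == "conditional"]
    assert len(conds) == 4  # only 4 of the 8 conditionals fit in one tree
    assert {e.quantity for e in g.edges if e.role == "marginal"} == first_margins


def test_tree_b_first_branches(mam_situation):
    g = build_tree(mam_situation, mode="prob", orientation="B_first")
    vals = {str(e.quantity): e.value for e in g.edges}
    assert vals["P(A|B)"] == F(8, 57)
    assert vals["P(notA|B)"] == F(49, 57)


def test_tree_a_first_sensitivity_branch_and_node(mam_situation):
    g = build_tree(mam_situation, N=10_000, mode="both")
    e = g.edge("edge:P(B|A)")
    assert e.label == "80%"
    assert g.node("A&B").freq_value == 160


# ---------------------------------------------------------------------------
# 2x2 table

def test_two_by_two_frequency_grid(mam_situation):
    g = build_two_by_two(mam_situation, N=10_000, mode="freq")
    assert len(g.nodes) == 16 and g.edges == []
    cells = {n.id: n.freq_value for n in g.nodes if n.role == "cell"}
    assert cells == {"A&B": 160, "A&notB": 40, "notA&B": 980,
                     "notA&notB": 8820}
    margins = {n.id: n.freq_value for n in g.nodes if n.role == "margin"}
    assert margins == {"A": 200, "notA": 9800, "B": 1140, "notB": 8860}
    assert g.node("total").freq_value == 10_000


def test_two_by_two_probability_mode_has_no_conditionals(mam_situation):
    g = build_two_by_two(mam_situation, mode="prob")
    assert all(e.role != "conditional" for e in g.edges)
    labels = {n.id: n.prob_label for n in g.nodes if n.role == "cell"}
    assert labels == {"A&B": "1.6%", "A&notB": "0.4%", "notA&B": "9.8%",
                      "notA&notB": "88.2%"}
    assert all(n.freq_label is None for n in g.nodes)


# ---------------------------------------------------------------------------
# text rendering

def test_render_text_net_has_nine_node_boxes(mam_situation):
    g = build_net(mam_situation, N=10_000, mode="freq")
    text = render_text(g)
    grid = text.split("branches:")[0]
    assert grid.count("[") == 9
    assert render_text(g) == text  # deterministic


def test_render_text_two_by_two_contains_all_nine_counts(mam_situation):
    text = render_text(build_two_by_two(mam_situation, N=10_000, mode="freq"))
    for count in ("160", "40", "980", "8,820", "200", "9,800", "1,140",
                  "8,860", "10,000"):
        assert count in text


def test_render_text_marks_crossing_branches(mam_situation):
    text = render_text(build_double_tree(mam_situation, mode="prob"))
    assert text.count("--x--") == 2


def test_every_label_appears_exactly_once(mam_situation):
    g = build_double_tree(mam_situation, N=10_000, mode="both")
    text = render_text(g)
    for e in g.edges:
        if e.label:
            assert text.count(f"{e.quantity} = {e.label}") == 1


# ---------------------------------------------------------------------------
# SVG rendering

def test_svg_net_structure(mam_situation):
    g = build_net(mam_situation, N=10_000, mode="both")
    svg = render_svg(g)
    root = ET.fromstring(svg)
    lines = root.findall(f"{SVG}line")
    assert len(lines) == 16
    assert {ln.get("id") for ln in lines} == {e.id for e in g.edges}
    dashed = [ln for ln in lines if ln.get("stroke-dasharray")]
    assert {ln.get("id") for ln in dashed} == {
        e.id for e in g.edges if e.role == "joint"
    }
    assert render_svg(g) == svg  # deterministic


def test_svg_default_double_tree_upward_labels_collide(mam_situation):
    """The default layout reproduces the crossing-band ambiguity: both
    upward labels anchor at the same point."""
    g = build_double_tree(mam_situation, mode="prob")
    root = ET.fromstring(render_svg(g))
    anchors = {
        t.get("id"): (float(t.get("x")), float(t.get("y")))
        for t in root.findall(f"{SVG}text") if t.get("id", "").startswith("label2:")
    }
    a = anchors["label2:edge:P(notB|A)"]
    b = anchors["label2:edge:P(B|notA)"]
    assert a == b


def test_svg_disambiguated_layout_separates_crossing_labels(mam_situation):
    layout = SvgLayout(min_label_separation=40.0)
    g = build_double_tree(mam_situation, mode="prob", layout="disambiguated")
    root = ET.fromstring(render_svg(g, layout))
    anchors = {
        t.get("id"): (float(t.get("x")), float(t.get("y")))
        for t in root.findall(f"{SVG}text") if t.get("id", "").startswith("label2:")
    }
    a = anchors["label2:edge:P(notB|A)"]
    b = anchors["label2:edge:P(B|notA)"]
    dist = ((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2) ** 0.5
    assert dist >= layout.min_label_separation
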