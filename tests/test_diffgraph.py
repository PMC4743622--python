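"""Reaction-network extraction, overlay and graph exports."""

import io
import json

import networkx as nx
import pytest

from modeldiff.core import diff
from modeldiff.diffgraph import (
    DiffNetwork,
    NetworkNotSupportedError,
    export_graph,
    extract_network,
    overlay_networks,
)
from modeldiff.fixtures import make_role_change_pair, random_model
from modeldiff.mapping import compute_mapping
from modeldiff.xmltree import parse_document

CELLML_NS = "http://www.cellml.org/cellml/1.0#"

SIMPLE_SBML = """<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="m">
    <listOfSpecies>
      <species id="C"/><species id="D"/><species id="E"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="reaction1" reversible="true">
        <listOfReactants>
          <speciesReference species="C"/>
          <speciesReference species="D"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="E"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


class TestExtraction:
    def test_reaction_yields_role_edges(self):
        net = extract_network(parse_document(SIMPLE_SBML))
        assert {n.id for n in net.nodes.values()} == {"s:C", "s:D", "s:E", "r:reaction1"}
        edges = {(e.source, e.target, e.role) for e in net.edges}
        assert edges == {
            ("s:C", "r:reaction1", "reactant"),
            ("s:D", "r:reaction1", "reactant"),
            ("r:reaction1", "s:E", "product"),
        }

    def test_species_only_model_has_no_edges(self):
        xml = '<sbml><model><listOfSpecies><species id="a"/></listOfSpecies></model></sbml>'
        net = extract_network(parse_document(xml))
        assert len(net.nodes) == 1 and net.edges == []

    def test_modifier_reference_becomes_modifier_edge(self):
        v1, _ = make_role_change_pair()
        net = extract_network(parse_document(v1))
        roles = {(e.source, e.role) for e in net.edges}
        assert ("s:cdc2", "modifier") in roles

    def test_generic_document_is_not_supported(self):
        with pytest.raises(NetworkNotSupportedError):
            extract_network(parse_document("<data><row/></data>"))

    def test_cellml_variable_ref_roles(self):
        xml = (
            f'<model xmlns="{CELLML_NS}" name="m"><component name="c">'
            '<variable name="A" units="molar"/><variable name="B" units="molar"/>'
            "<reaction>"
            '<variable_ref variable="A"><role role="reactant"/></variable_ref>'
            '<variable_ref variable="B"><role role="product"/></variable_ref>'
            "</reaction></component></model>"
        )
        net = extract_network(parse_document(xml))
        kinds = sorted(n.kind for n in net.nodes.values())
        assert kinds == ["reaction", "species", "species"]
        assert {(e.role) for e in net.edges} == {"reactant", "product"}


def role_change_overlay():
    v1, v2 = make_role_change_pair()
    result = diff(v1, v2)
    n1 = extract_network(result.t1)
    n2 = extract_network(result.t2)
    return overlay_networks(n1, n2, result.mapping)


class TestOverlay:
    def test_identical_versions_are_all_unchanged(self):
        xml = random_model(11, n_species=4, n_reactions=2)
        t1, t2 = parse_document(xml), parse_document(xml)
        mapping = compute_mapping(t1, t2)
        overlay = overlay_networks(extract_network(t1), extract_network(t2), mapping)
        assert all(n.origin == "both" and n.status == "unchanged" for n in overlay.nodes)
        assert all(e.origin == "both" and e.status == "unchanged" for e in overlay.edges)

    def test_role_change_gives_deleted_and_inserted_edge(self):
        overlay = role_change_overlay()
        statuses = {(e.role, e.status) for e in overlay.edges}
        assert ("modifier", "deleted") in statuses
        assert ("reactant", "inserted") in statuses
        reaction = next(n for n in overlay.nodes if n.kind == "reaction")
        assert reaction.origin == "both" and reaction.status == "updated"

    def test_version_exclusive_species_statuses(self):
        v1 = '<sbml><model><listOfSpecies><species id="gone"/><species id="kept"/></listOfSpecies></model></sbml>'
        v2 = '<sbml><model><listOfSpecies><species id="kept"/><species id="fresh"/></listOfSpecies></model></sbml>'
        result = diff(v1, v2)
        overlay = overlay_networks(
            extract_network(result.t1), extract_network(result.t2), result.mapping
        )
        by_label = {n.label: (n.origin, n.status) for n in overlay.nodes}
        assert by_label["gone"] == ("v1-only", "deleted")
        assert by_label["fresh"] == ("v2-only", "inserted")
        assert by_label["kept"] == ("both", "unchanged")


class TestExports:
    def test_graphml_round_trips_through_independent_reader(self):
        overlay = role_change_overlay()
        text = export_graph(overlay, "graphml")
        graph = nx.read_graphml(io.BytesIO(text.encode()))
        assert graph.number_of_nodes() == len(overlay.nodes)
        assert graph.number_of_edges() == len(overlay.edges)
        statuses = nx.get_node_attributes(graph, "status")
        assert "updated" in statuses.values()

    def test_json_schema_has_origin_status_role(self):
        overlay = role_change_overlay()
        payload = json.loads(export_graph(overlay, "json"))
        assert set(payload) == {"nodes", "edges"}
        for node in payload["nodes"]:
            assert {"id", "label", "kind", "origin", "status", "color"} <= set(node)
        for edge in payload["edges"]:
            assert {"source", "target", "role", "origin", "status"} <= set(edge)

    def test_dot_output_is_a_digraph_with_colored_edges(self):
        overlay = role_change_overlay()
        text = export_graph(overlay, "dot")
        assert text.startswith("digraph")
        assert "->" in text
        assert 'color="red"' in text  # the deleted modifier edge
        assert 'color="blue"' in text  # the inserted reactant edge

    def test_default_colors_follow_the_network_convention(self):
        overlay = role_change_overlay()
        payload = json.loads(export_graph(overlay, "json"))
        colors = {e["status"]: e["color"] for e in payload["edges"]}
        assert colors["deleted"] == "red"
        assert colors["inserted"] == "blue"

    def test_custom_color_map_is_honoured(self):
        overlay = role_change_overlay()
        payload = json.loads(export_graph(overlay, "json", colors={"inserted": "green"}))
        colors = {e["status"]: e["color"] for e in payload["edges"]}
        assert colors["inserted"] == "green"

    def test_empty_network_exports_are_minimal_but_valid(self):
        empty = DiffNetwork()
        graph = nx.read_graphml(io.BytesIO(export_graph(empty, "graphml").encode()))
        assert graph.number_of_nodes() == 0
        assert json.loads(export_graph(empty, "json")) == {"nodes": [], "edges": []}
        assert export_graph(empty, "dot").startswith("digraph")

    def test_node_and_edge_counts_conserved_across_formats(self):
        overlay = role_change_overlay()
        graphml = nx.read_graphml(io.BytesIO(export_graph(overlay, "graphml").encode()))
        payload = json.loads(export_graph(overlay, "json"))
        dot = export_graph(overlay, "dot")
        dot_edges = dot.count("->")
        assert (
            graphml.number_of_edges()
            == len(payload["edges"])
            == dot_edges
            == len(overlay.edges)
        )
        assert graphml.number_of_nodes() == len(payload["nodes"]) == len(overlay.nodes)

    def test_unknown_format_is_a_usage_error(self):
        with pytest.raises(ValueError, match="unknown graph format"):
            export_graph(DiffNetwork(), "svg")
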