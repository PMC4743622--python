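"""Reaction-network extraction, version overlay, and graph export.

The reaction network of a model is a bipartite graph: species nodes and
reaction nodes connected by directed role edges (reactant, product,
modifier).  Both versions' networks are merged via the node mapping into a
single :class:`DiffNetwork` whose nodes and edges know which version they
come from (``both``, ``v1-only``, ``v2-only``) and what happened to them
(``unchanged``, ``updated``, ``inserted``, ``deleted``).  The overlay can be
exported as GraphML, DOT or JSON with a colour map highlighting the changes
(deletes red, inserts blue, updates yellow by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .domainrules import detect_dialect
from .mapping import NodeMapping
from .xmltree import DocNode, DocTree

__all__ = [
    "ReactionNetwork",
    "DiffNetwork",
    "NetworkNotSupportedError",
    "extract_network",
    "overlay_networks",
    "export_graph",
    "DEFAULT_COLORS",
    "GRAPH_FORMATS",
]

GRAPH_FORMATS = ("graphml", "dot", "json")

DEFAULT_COLORS = {
    "deleted": "red",
    "inserted": "blue",
    "updated": "yellow",
    "unchanged": "black",
}


class NetworkNotSupportedError(ValueError):
    """The document does not encode an extractable reaction network."""


@dataclass
class NetNode:
    id: str
    label: str
    kind: str  # species | reaction
    doc_node: Optional[DocNode] = None


@dataclass(frozen=True)
class NetEdge:
    source: str  # network node id
    target: str
    role: str  # reactant | product | modifier
    stoichiometry: Optional[str] = None


@dataclass
class ReactionNetwork:
    """Species/reaction nodes plus directed role edges of one model version."""

    nodes: dict = field(default_factory=dict)  # id -> NetNode
    edges: list = field(default_factory=list)

    def add_node(self, node: NetNode) -> None:
        if node.id in self.nodes:
            raise ValueError(f"duplicate network node id {node.id!r}")
        self.nodes[node.id] = node

    def add_edge(self, edge: NetEdge) -> None:
        src, dst = self.nodes[edge.source], self.nodes[edge.target]
        if {src.kind, dst.kind} != {"species", "reaction"}:
            raise ValueError("edges must connect a species node and a reaction node")
        self.edges.append(edge)


@dataclass
class DiffNode:
    id: str
    label: str
    kind: str
    origin: str  # both | v1-only | v2-only
    status: str  # unchanged | updated | inserted | deleted


@dataclass(frozen=True)
class DiffEdge:
    source: str
    target: str
    role: str
    origin: str
    status: str
    stoichiometry: Optional[str] = None


@dataclass
class DiffNetwork:
    """Overlay of two reaction networks with per-element change status."""

    nodes: list = field(default_factory=list)
    edges: list = field(default_factory=list)


# -- extraction ------------------------------------------------------------


def _find(node: DocNode, name: str):
    for child in node.children:
        if not child.is_text and child.local_name == name:
            yield child


def _attr(node: DocNode, name: str) -> Optional[str]:
    for key, value in node.attributes.items():
        if key.split("}")[-1] == name:
            return value
    return None


def _label_of(node: DocNode) -> str:
    from .xmltree import xpath_of

    return _attr(node, "name") or _attr(node, "id") or xpath_of(node)


def _extract_sbml(tree: DocTree) -> ReactionNetwork:
    net = ReactionNetwork()
    species_elements = [
        n
        for n in tree.nodes
        if not n.is_text
        and n.local_name == "species"
        and n.parent is not None
        and n.parent.local_name == "listOfSpecies"
    ]
    species_by_id: dict[str, str] = {}
    for i, sp in enumerate(species_elements, start=1):
        sid = _attr(sp, "id") or _attr(sp, "name") or f"species_{i}"
        net.add_node(NetNode(id=f"s:{sid}", label=_label_of(sp), kind="species", doc_node=sp))
        if _attr(sp, "id"):
            species_by_id[_attr(sp, "id")] = f"s:{sid}"
    reactions = [
        n
        for n in tree.nodes
        if not n.is_text
        and n.local_name == "reaction"
        and n.parent is not None
        and n.parent.local_name == "listOfReactions"
    ]
    role_lists = (
        ("listOfReactants", "speciesReference", "reactant"),
        ("listOfProducts", "speciesReference", "product"),
        ("listOfModifiers", "modifierSpeciesReference", "modifier"),
    )
    for i, rx in enumerate(reactions, start=1):
        rid = _attr(rx, "id") or f"reaction_{i}"
        node_id = f"r:{rid}"
        net.add_node(NetNode(id=node_id, label=_label_of(rx), kind="reaction", doc_node=rx))
        for list_tag, ref_tag, role in role_lists:
            for holder in _find(rx, list_tag):
                for ref in _find(holder, ref_tag):
                    target = _attr(ref, "species")
                    if target is None or target not in species_by_id:
                        continue
                    species_id = species_by_id[target]
                    stoich = _attr(ref, "stoichiometry")
                    if role == "product":
                        net.add_edge(NetEdge(node_id, species_id, role, stoich))
                    else:
                        net.add_edge(NetEdge(species_id, node_id, role, stoich))
    return net


def _extract_cellml(tree: DocTree) -> ReactionNetwork:
    net = ReactionNetwork()
    found_reaction = False
    for component in (n for n in tree.nodes if not n.is_text and n.local_name == "component"):
        cname = _attr(component, "name") or "component"
        variables = {
            _attr(v, "name"): v for v in _find(component, "variable") if _attr(v, "name")
        }
        for i, reaction in enumerate(_find(component, "reaction"), start=1):
            found_reaction = True
            rid = f"r:{cname}:{i}"
            net.add_node(NetNode(id=rid, label=f"{cname} reaction {i}", kind="reaction", doc_node=reaction))
            for ref in _find(reaction, "variable_ref"):
                vname = _attr(ref, "variable")
                if vname is None:
                    continue
                sid = f"s:{cname}:{vname}"
                if sid not in net.nodes:
                    net.add_node(
                        NetNode(
                            id=sid,
                            label=vname,
                            kind="species",
                            doc_node=variables.get(vname, ref),
                        )
                    )
                for role_el in _find(ref, "role"):
                    role = _attr(role_el, "role") or "reactant"
                    if role not in ("reactant", "product", "modifier"):
                        continue
                    if role == "product":
                        net.add_edge(NetEdge(rid, sid, role))
                    else:
                        net.add_edge(NetEdge(sid, rid, role))
    if not found_reaction and not net.nodes:
        raise NetworkNotSupportedError(
            "CellML document contains no reaction markup to extract"
        )
    return net


def extract_network(tree: DocTree) -> ReactionNetwork:
    """Extract the reaction network of an SBML or CellML document."""
    dialect = detect_dialect(tree)
    if dialect == "sbml":
        return _extract_sbml(tree)
    if dialect == "cellml":
        return _extract_cellml(tree)
    raise NetworkNotSupportedError(
        "reaction-network extraction supports SBML and CellML documents only"
    )


# -- overlay ---------------------------------------------------------------


def overlay_networks(
    n1: ReactionNetwork, n2: ReactionNetwork, mapping: NodeMapping
) -> DiffNetwork:
    """Merge two version networks into one difference-highlighted network.

    Species/reaction nodes whose underlying document nodes are paired merge
    into a single node (origin ``both``); everything else is version-local.
    A merged node counts as updated when its document node's attributes
    changed or its incident edge set differs between the versions.
    """
    merged = DiffNetwork()
    doc_to_net1 = {id(node.doc_node): node for node in n1.nodes.values() if node.doc_node}
    id_map_2to1: dict[str, str] = {}
    for node2 in n2.nodes.values():
        partner_doc = mapping.partner_in_t1(node2.doc_node) if node2.doc_node else None
        partner = doc_to_net1.get(id(partner_doc)) if partner_doc is not None else None
        if partner is not None and partner.kind == node2.kind:
            id_map_2to1[node2.id] = partner.id

    edges1 = {(e.source, e.target, e.role): e for e in n1.edges}
    edges2 = {
        (
            id_map_2to1.get(e.source, f"v2:{e.source}"),
            id_map_2to1.get(e.target, f"v2:{e.target}"),
            e.role,
        ): e
        for e in n2.edges
    }

    changed_nodes: set[str] = set()
    for key in set(edges1) | set(edges2):
        for endpoint in key[:2]:
            if (key in edges1) != (key in edges2):
                changed_nodes.add(endpoint)

    mapped_ids_1 = set(id_map_2to1.values())
    for node1 in n1.nodes.values():
        if node1.id in mapped_ids_1:
            node2 = next(
                n2.nodes[i2] for i2, i1 in id_map_2to1.items() if i1 == node1.id
            )
            attrs_changed = (
                node1.doc_node is not None
                and node2.doc_node is not None
                and node1.doc_node.attributes != node2.doc_node.attributes
            )
            status = "updated" if attrs_changed or node1.id in changed_nodes else "unchanged"
            merged.nodes.append(
                DiffNode(node1.id, node1.label, node1.kind, "both", status)
            )
        else:
            merged.nodes.append(
                DiffNode(node1.id, node1.label, node1.kind, "v1-only", "deleted")
            )
    for node2 in n2.nodes.values():
        if node2.id not in id_map_2to1:
            merged.nodes.append(
                DiffNode(f"v2:{node2.id}", node2.label, node2.kind, "v2-only", "inserted")
            )

    for key in sorted(set(edges1) | set(edges2)):
        source, target, role = key
        in1, in2 = key in edges1, key in edges2
        stoich = (edges1[key] if in1 else edges2[key]).stoichiometry
        if in1 and in2:
            status, origin = "unchanged", "both"
            if edges1[key].stoichiometry != edges2[key].stoichiometry:
                status = "updated"
        elif in1:
            status, origin = "deleted", "v1-only"
        else:
            status, origin = "inserted", "v2-only"
        merged.edges.append(DiffEdge(source, target, role, origin, status, stoich))
    return merged


# -- export ----------------------------------------------------------------

_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"

_NODE_KEYS = ("label", "kind", "origin", "status", "color")
_EDGE_KEYS = ("role", "origin", "status", "color", "stoichiometry")


def _export_graphml(net: DiffNetwork, colors: dict) -> str:
    root = etree.Element(f"{{{_GRAPHML_NS}}}graphml", nsmap={None: _GRAPHML_NS})
    key_ids = {}
    for i, (target, name) in enumerate(
        [("node", k) for k in _NODE_KEYS] + [("edge", k) for k in _EDGE_KEYS]
    ):
        key = etree.SubElement(root, f"{{{_GRAPHML_NS}}}key")
        key.set("id", f"d{i}")
        key.set("for", target)
        key.set("attr.name", name)
        key.set("attr.type", "string")
        key_ids[(target, name)] = f"d{i}"
    graph = etree.SubElement(root, f"{{{_GRAPHML_NS}}}graph")
    graph.set("id", "diff")
    graph.set("edgedefault", "directed")

    def put(parent, target, name, value):
        if value is None:
            return
        data = etree.SubElement(parent, f"{{{_GRAPHML_NS}}}data")
        data.set("key", key_ids[(target, name)])
        data.text = value

    for node in net.nodes:
        el = etree.SubElement(graph, f"{{{_GRAPHML_NS}}}node")
        el.set("id", node.id)
        put(el, "node", "label", node.label)
        put(el, "node", "kind", node.kind)
        put(el, "node", "origin", node.origin)
        put(el, "node", "status", node.status)
        put(el, "node", "color", colors.get(node.status, "black"))
    for i, edge in enumerate(net.edges):
        el = etree.SubElement(graph, f"{{{_GRAPHML_NS}}}edge")
        el.set("id", f"e{i}")
        el.set("source", edge.source)
        el.set("target", edge.target)
        put(el, "edge", "role", edge.role)
        put(el, "edge", "origin", edge.origin)
        put(el, "edge", "status", edge.status)
        put(el, "edge", "color", colors.get(edge.status, "black"))
        put(el, "edge", "stoichiometry", edge.stoichiometry)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def _dot_quote(value: str) -> str:
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _export_dot(net: DiffNetwork, colors: dict) -> str:
    lines = ["digraph diff {"]
    for node in net.nodes:
        shape = "ellipse" if node.kind == "species" else "box"
        attrs = (
            f"label={_dot_quote(node.label)}, shape={shape}, "
            f"color={_dot_quote(colors.get(node.status, 'black'))}, "
            f"origin={_dot_quote(node.origin)}, status={_dot_quote(node.status)}"
        )
        lines.append(f"  {_dot_quote(node.id)} [{attrs}];")
    for edge in net.edges:
        attrs = (
            f"label={_dot_quote(edge.role)}, "
            f"color={_dot_quote(colors.get(edge.status, 'black'))}, "
            f"origin={_dot_quote(edge.origin)}, status={_dot_quote(edge.status)}"
        )
        if edge.stoichiometry is not None:
            attrs += f", stoichiometry={_dot_quote(edge.stoichiometry)}"
        lines.append(f"  {_dot_quote(edge.source)} -> {_dot_quote(edge.target)} [{attrs}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def _export_json(net: DiffNetwork, colors: dict) -> str:
    payload = {
        "nodes": [
            {
                "id": node.id,
                "label": node.label,
                "kind": node.kind,
                "origin": node.origin,
                "status": node.status,
                "color": colors.get(node.status, "black"),
            }
            for node in net.nodes
        ],
        "edges": [
            {
                "source": edge.source,
                "target": edge.target,
                "role": edge.role,
                "origin": edge.origin,
                "status": edge.status,
                "color": colors.get(edge.status, "black"),
                **(
                    {"stoichiometry": edge.stoichiometry}
                    if edge.stoichiometry is not None
                    else {}
                ),
            }
            for edge in net.edges
        ],
    }
    return json.dumps(payload, indent=2) + "\n"


def export_graph(net: DiffNetwork, format: str = "graphml", colors: Optional[dict] = None) -> str:
    """Serialise a difference network as GraphML, DOT or JSON text."""
    if format not in GRAPH_FORMATS:
        raise ValueError(
            f"unknown graph format {format!r}; expected one of {', '.join(GRAPH_FORMATS)}"
        )
    palette = dict(DEFAULT_COLORS)
    if colors:
        palette.update(colors)
    if format == "graphml":
        return _export_graphml(net, palette)
    if format == "dot":
        return _export_dot(net, palette)
    return _export_json(net, palette)
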