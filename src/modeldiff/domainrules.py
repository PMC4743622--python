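"""SBML/CellML-specific post-processing of the node mapping.

Certain parts of a model are atomic: a ``speciesReference`` belongs to its
reaction, a ``variable`` to its component, a ``listOf*`` container to its
parent.  A correspondence between two such nodes whose parents do not
correspond would let a delta "move" structure across unrelated entities, so
those pairs are dropped (together with the pairs of their descendants — a
detached subtree cannot remain partially mapped).  Dropping pairs enlarges
the delta, trading minimality for biological significance.
"""

from __future__ import annotations

from .mapping import NodeMapping
from .xmltree import DocNode, DocTree

__all__ = [
    "detect_dialect",
    "apply_sbml_rules",
    "apply_cellml_rules",
    "apply_domain_rules",
    "SBML_GLUED_TAGS",
    "CELLML_GLUED_TAGS",
]

SBML_GLUED_TAGS = frozenset(
    {
        "speciesReference",
        "modifierSpeciesReference",
        "trigger",
        "eventAssignment",
        "delay",
        "priority",
    }
)

CELLML_GLUED_TAGS = frozenset({"variable", "reaction"})


def detect_dialect(tree: DocTree) -> str:
    """Classify a document as ``sbml``, ``cellml`` or ``generic``."""
    root = tree.root
    namespace = root.tag[1:].split("}", 1)[0] if root.tag.startswith("{") else ""
    if root.local_name == "sbml" or "sbml.org" in namespace:
        return "sbml"
    if root.local_name == "model" and "cellml" in namespace.lower():
        return "cellml"
    return "generic"


def _parents_paired(n1: DocNode, n2: DocNode, mapping: NodeMapping) -> bool:
    if n1.parent is None or n2.parent is None:
        return n1.parent is None and n2.parent is None
    return mapping.are_paired(n1.parent, n2.parent)


def _drop_pair_with_descendants(n1: DocNode, mapping: NodeMapping) -> None:
    for node in n1.iter():
        if mapping.has_t1(node):
            mapping.remove(node)


def _apply_glue(
    mapping: NodeMapping, is_glued
) -> NodeMapping:
    changed = True
    while changed:
        changed = False
        for n1, n2 in list(mapping.pairs()):
            if not mapping.are_paired(n1, n2):  # dropped in an earlier cascade
                continue
            if n1.parent is None:  # root pair is never glued
                continue
            if is_glued(n1) and not _parents_paired(n1, n2, mapping):
                _drop_pair_with_descendants(n1, mapping)
                changed = True
    return mapping


def _sbml_glued(node: DocNode) -> bool:
    name = node.local_name
    return name.startswith("listOf") or name in SBML_GLUED_TAGS


def apply_sbml_rules(mapping: NodeMapping) -> NodeMapping:
    """Drop pairs of listOf* containers and reaction-/event-glued nodes whose
    parents are not paired with each other."""
    return _apply_glue(mapping, _sbml_glued)


def _cellml_component_of(node: DocNode):
    for ancestor in node.ancestors():
        if ancestor.local_name == "component":
            return ancestor
    return None


def apply_cellml_rules(mapping: NodeMapping) -> NodeMapping:
    """Drop variable/reaction pairs whose enclosing components are not paired."""
    changed = True
    while changed:
        changed = False
        for n1, n2 in list(mapping.pairs()):
            if not mapping.are_paired(n1, n2):
                continue
            if n1.is_text or n1.local_name not in CELLML_GLUED_TAGS:
                continue
            c1, c2 = _cellml_component_of(n1), _cellml_component_of(n2)
            if c1 is None and c2 is None:
                continue
            if c1 is None or c2 is None or not mapping.are_paired(c1, c2):
                _drop_pair_with_descendants(n1, mapping)
                changed = True
    return mapping


def apply_domain_rules(dialect: str, mapping: NodeMapping) -> NodeMapping:
    """Apply the rule set matching the detected dialect (no-op for generic)."""
    if dialect == "sbml":
        return apply_sbml_rules(mapping)
    if dialect == "cellml":
        return apply_cellml_rules(mapping)
    return mapping
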