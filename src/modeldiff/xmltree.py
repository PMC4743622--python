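"""Internal document tree: parsing, weights, subtree signatures, node addressing.

An XML document is translated into a tree of :class:`DocNode` objects.  Every
node carries

* a **weight** ω measuring the size of the subtree it roots (leaf elements
  count 1, text contributes logarithmically, inner nodes sum their children),
  used to prioritise large subtrees during matching and to score mapping
  suggestions, and
* a **signature** σ, a SHA-256 digest of the subtree's canonical content
  (expanded tag name, attributes in canonical order, child digests in document
  order, normalised text).  Equal signatures identify identical subtrees, which
  is what makes hash-based subtree matching fast.

The canonical form deliberately ignores indentation/whitespace-only text,
attribute order, comments and processing instructions: none of these affect
the encoded model.  Namespace declarations (``xmlns*``) are not attributes of
the model content and are excluded from attribute sets and signatures; element
names are compared by expanded name (namespace URI + local name, Clark
notation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from hashlib import sha256
from typing import Iterator, Optional

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "DocNode",
    "DocTree",
    "ParseError",
    "parse_document",
    "compute_weights",
    "compute_signatures",
    "xpath_of",
    "resolve_path",
    "serialize_tree",
]

_SEP = "\x00"  # cannot occur in XML content, hence unambiguous


class ParseError(ValueError):
    """Raised for malformed or empty XML input."""


def local_name(tag: str) -> str:
    """Local part of a Clark-notation tag (``{uri}local`` -> ``local``)."""
    if tag.startswith("{"):
        return tag.split("}", 1)[1]
    return tag


class DocNode:
    """One element or text node of the internal tree.

    ``tag`` holds the expanded (Clark-notation) element name and is the empty
    string for text nodes.  ``weight`` and ``signature`` are filled in by
    :func:`compute_weights` / :func:`compute_signatures`.
    """

    __slots__ = (
        "tag",
        "attributes",
        "text",
        "children",
        "parent",
        "weight",
        "signature",
        "doc_order",
    )

    def __init__(self, tag: str = "", attributes: Optional[dict] = None, text: str = ""):
        self.tag = tag
        self.attributes: dict[str, str] = dict(attributes or {})
        self.text = text
        self.children: list[DocNode] = []
        self.parent: Optional[DocNode] = None
        self.weight: float = 0.0
        self.signature: str = ""
        self.doc_order: int = -1

    # -- structural helpers -------------------------------------------------

    @property
    def is_text(self) -> bool:
        return self.tag == ""

    @property
    def local_name(self) -> str:
        return local_name(self.tag)

    @property
    def text_length(self) -> int:
        return len(self.text)

    @property
    def child_index(self) -> int:
        """1-based position among the parent's retained children."""
        if self.parent is None:
            return 1
        return self.parent.children.index(self) + 1

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    def append(self, child: "DocNode") -> None:
        child.parent = self
        self.children.append(child)

    def insert(self, index: int, child: "DocNode") -> None:
        child.parent = self
        self.children.insert(index, child)

    def detach(self) -> None:
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None

    def iter(self) -> Iterator["DocNode"]:
        """Preorder traversal of the subtree rooted here."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_postorder(self) -> Iterator["DocNode"]:
        for child in self.children:
            yield from child.iter_postorder()
        yield self

    def ancestors(self) -> Iterator["DocNode"]:
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def clone(self) -> "DocNode":
        dup = DocNode(self.tag, dict(self.attributes), self.text)
        for child in self.children:
            dup.append(child.clone())
        return dup

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_text:
            return f"<DocNode text {self.text!r}>"
        return f"<DocNode {self.local_name!r} ω={self.weight:g}>"


@dataclass
class DocTree:
    """A parsed document: root node plus the indices the matcher relies on."""

    root: DocNode
    id_index: dict = field(default_factory=dict)
    signature_index: dict = field(default_factory=dict)
    nodes: list = field(default_factory=list)
    height: int = 0

    @property
    def root_weight(self) -> float:
        return self.root.weight

    def reindex(self) -> "DocTree":
        """Recompute document order, weights, signatures and all indices."""
        self.nodes = list(self.root.iter())
        for order, node in enumerate(self.nodes):
            node.doc_order = order
        compute_weights(self)
        compute_signatures(self)
        self.height = max((n.depth for n in self.nodes), default=0)
        self._build_id_index()
        return self

    def _build_id_index(self) -> None:
        seen: dict[str, list[DocNode]] = {}
        for node in self.nodes:
            if node.is_text:
                continue
            for name, value in node.attributes.items():
                if local_name(name) == "id":
                    seen.setdefault(value, []).append(node)
        self.id_index = {}
        for value, owners in seen.items():
            if len(owners) == 1:
                self.id_index[value] = owners[0]
            else:
                logger.warning(
                    "duplicate id %r occurs %d times; excluded from id index",
                    value,
                    len(owners),
                )

    def canonically_equal(self, other: "DocTree") -> bool:
        return self.root.signature == other.root.signature

    def copy(self) -> "DocTree":
        return DocTree(self.root.clone()).reindex()


# -- parsing ---------------------------------------------------------------


def _convert(element: etree._Element) -> DocNode:
    node = DocNode(element.tag, dict(element.attrib))
    if element.text and element.text.strip():
        node.append(DocNode(text=element.text.strip()))
    for child in element:
        node.append(_convert(child))
        if child.tail and child.tail.strip():
            node.append(DocNode(text=child.tail.strip()))
    return node


def parse_document(xml_text) -> DocTree:
    """Parse XML text into a :class:`DocTree` with weights and signatures.

    Whitespace-only text nodes, comments and processing instructions are
    discarded; remaining text is stripped of surrounding whitespace.  External
    entity resolution and network access are disabled.
    """
    if isinstance(xml_text, str):
        data = xml_text.encode("utf-8")
    else:
        data = bytes(xml_text)
    if not data.strip():
        raise ParseError("empty input: no XML document found")
    parser = etree.XMLParser(
        resolve_entities=False,
        no_network=True,
        remove_comments=True,
        remove_pis=True,
        huge_tree=False,
    )
    try:
        root = etree.fromstring(data, parser=parser)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    return DocTree(_convert(root)).reindex()


# -- weights ---------------------------------------------------------------


def compute_weights(tree: DocTree) -> DocTree:
    """Assign the subtree-size weight ω to every node.

    Text nodes weigh ``1 + log(length)`` (natural logarithm), childless
    elements weigh 1, and inner elements weigh one plus the sum of their
    children's weights — so a parent always outweighs each of its children.
    """
    for node in tree.root.iter_postorder():
        if node.is_text:
            node.weight = 1.0 + math.log(max(node.text_length, 1))
        elif not node.children:
            node.weight = 1.0
        else:
            node.weight = 1.0 + sum(c.weight for c in node.children)
    return tree


# -- signatures ------------------------------------------------------------


def _node_digest(node: DocNode) -> str:
    if node.is_text:
        payload = "t" + _SEP + node.text
    else:
        attrs = _SEP.join(
            f"{name}={value}" for name, value in sorted(node.attributes.items())
        )
        kids = "".join(child.signature for child in node.children)
        payload = "e" + _SEP + node.tag + _SEP + attrs + _SEP + kids
    return sha256(payload.encode("utf-8")).hexdigest()


def compute_signatures(tree: DocTree) -> DocTree:
    """Assign canonical SHA-256 subtree signatures and build the signature index."""
    index: dict[str, list[DocNode]] = {}
    for node in tree.root.iter_postorder():
        node.signature = _node_digest(node)
    for node in tree.root.iter():  # document order within each bucket
        index.setdefault(node.signature, []).append(node)
    tree.signature_index = index
    return tree


# -- node addressing -------------------------------------------------------


class DetachedNodeError(ValueError):
    """Raised when a path is requested for a node not attached to the tree."""


def _step_of(node: DocNode) -> str:
    if node.parent is None:
        return f"/{node.local_name}[1]"
    if node.is_text:
        siblings = [c for c in node.parent.children if c.is_text]
        return f"text()[{siblings.index(node) + 1}]"
    siblings = [
        c
        for c in node.parent.children
        if not c.is_text and c.local_name == node.local_name
    ]
    return f"{node.local_name}[{siblings.index(node) + 1}]"


def xpath_of(node: DocNode, tree: Optional[DocTree] = None) -> str:
    """Absolute XPath with 1-based positional predicates selecting this node.

    Steps use local element names (``/sbml[1]/model[1]/species[2]``); text
    nodes end in a ``text()[k]`` step.
    """
    steps = []
    current = node
    while current.parent is not None:
        steps.append(_step_of(current))
        current = current.parent
    if current.is_text:
        raise DetachedNodeError("text node is not attached to a document tree")
    if tree is not None and current is not tree.root:
        raise DetachedNodeError("node is not attached to the given tree")
    steps.append(_step_of(current))
    return "/".join(reversed(steps))


def resolve_path(tree: DocTree, path: str) -> DocNode:
    """Resolve a path produced by :func:`xpath_of` against a tree.

    Raises :class:`KeyError` if any step fails to select a node.
    """
    if not path.startswith("/"):
        raise KeyError(f"path must be absolute: {path!r}")
    steps = path.lstrip("/").split("/")
    name, idx = _parse_step(steps[0], path)
    if tree.root.local_name != name or idx != 1:
        raise KeyError(f"root step {steps[0]!r} does not match document root")
    node = tree.root
    for step in steps[1:]:
        name, idx = _parse_step(step, path)
        if name == "text()":
            candidates = [c for c in node.children if c.is_text]
        else:
            candidates = [
                c for c in node.children if not c.is_text and c.local_name == name
            ]
        if idx < 1 or idx > len(candidates):
            raise KeyError(f"step {step!r} of {path!r} selects nothing")
        node = candidates[idx - 1]
    return node


def _parse_step(step: str, path: str) -> tuple[str, int]:
    if not step.endswith("]") or "[" not in step:
        raise KeyError(f"step {step!r} of {path!r} lacks a positional predicate")
    name, _, pred = step.partition("[")
    try:
        idx = int(pred[:-1])
    except ValueError as exc:
        raise KeyError(f"non-integer predicate in step {step!r}") from exc
    return name, idx


# -- serialisation ---------------------------------------------------------


def _to_lxml(node: DocNode) -> etree._Element:
    element = etree.Element(node.tag, attrib=dict(sorted(node.attributes.items())))
    last_child = None
    for child in node.children:
        if child.is_text:
            if last_child is None:
                element.text = (element.text or "") + child.text
            else:
                last_child.tail = (last_child.tail or "") + child.text
        else:
            last_child = _to_lxml(child)
            element.append(last_child)
    return element


def serialize_tree(tree: DocTree, pretty: bool = True) -> str:
    """Serialise a :class:`DocTree` back to XML text (UTF-8, deterministic)."""
    element = _to_lxml(tree.root)
    return etree.tostring(element, pretty_print=pretty, encoding="unicode")
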