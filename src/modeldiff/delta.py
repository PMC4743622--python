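"""Delta derivation, XML serialisation, inversion and patching.

A delta is four disjoint sets of edit operations — *deletes*, *inserts*,
*moves* and *updates* — over nodes, attributes and text, sufficient to
transform one document version into the other.  Because every surviving,
inserted and deleted entity is addressed by explicit pre-/post-patch XPath
coordinates the delta is complete: it can be applied forwards, inverted and
applied backwards.

Operation semantics:

* unmapped nodes of T1 (and their attributes) become deletes, unmapped nodes
  of T2 become inserts;
* a mapped node whose parents are not paired with each other, or whose
  position among its mapped siblings changed, becomes a move (node entities
  only);
* per mapped pair, attributes present on one side only become
  deletes/inserts, differing values become updates; differing text content
  of a mapped text pair becomes a text update;
* a root tag rename is the only node-level update.

Sibling-sequence changes are detected with a longest-increasing-subsequence
pass over each pair's mapped children, so the number of emitted moves is
minimal and deterministic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Optional

from lxml import etree

from .mapping import NodeMapping
from .xmltree import DocNode, DocTree, resolve_path, xpath_of

__all__ = [
    "DeltaOperation",
    "Delta",
    "DeltaFormatError",
    "PatchError",
    "compute_delta",
    "serialize_delta",
    "parse_delta",
    "invert_delta",
    "patch",
]


class DeltaFormatError(ValueError):
    """Raised when a delta document violates the dialect."""


class PatchError(RuntimeError):
    """Raised when a delta cannot be applied to a document."""

    def __init__(self, message: str, op_id: Optional[str] = None):
        super().__init__(message if op_id is None else f"operation {op_id}: {message}")
        self.op_id = op_id


@dataclass(frozen=True)
class DeltaOperation:
    """One edit operation on a node, attribute or text entity."""

    op_kind: str  # insert | delete | move | update
    entity_kind: str  # node | attribute | text
    uid: str = ""
    old_path: Optional[str] = None
    new_path: Optional[str] = None
    old_parent: Optional[str] = None
    new_parent: Optional[str] = None
    old_child_no: Optional[int] = None
    new_child_no: Optional[int] = None
    old_tag: Optional[str] = None
    new_tag: Optional[str] = None
    attr_name: Optional[str] = None
    old_value: Optional[str] = None
    new_value: Optional[str] = None


@dataclass
class Delta:
    """The four disjoint operation sets plus source/target references."""

    deletes: list = field(default_factory=list)
    inserts: list = field(default_factory=list)
    moves: list = field(default_factory=list)
    updates: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.deletes) + len(self.inserts) + len(self.moves) + len(self.updates)

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    def operations(self):
        yield from self.deletes
        yield from self.inserts
        yield from self.moves
        yield from self.updates


# -- derivation ------------------------------------------------------------


def _lis_member_flags(sequence: list[int]) -> list[bool]:
    """Flags marking members of one longest strictly increasing subsequence."""
    if not sequence:
        return []
    tails: list[int] = []  # values
    tails_idx: list[int] = []
    prev = [-1] * len(sequence)
    for i, value in enumerate(sequence):
        pos = bisect.bisect_left(tails, value)
        if pos == len(tails):
            tails.append(value)
            tails_idx.append(i)
        else:
            tails[pos] = value
            tails_idx[pos] = i
        prev[i] = tails_idx[pos - 1] if pos > 0 else -1
    flags = [False] * len(sequence)
    i = tails_idx[-1]
    while i != -1:
        flags[i] = True
        i = prev[i]
    return flags


def compute_delta(t1: DocTree, t2: DocTree, mapping: NodeMapping) -> Delta:
    """Derive the complete delta from a finalized mapping."""
    if mapping.partner_in_t2(t1.root) is not t2.root:
        raise RuntimeError("mapping does not pair the two document roots")

    delta = Delta()
    uid_counter = 0

    def uid() -> str:
        nonlocal uid_counter
        uid_counter += 1
        return str(uid_counter)

    # --- unmapped T1 nodes: deletes (document order, deepest handled by patch)
    for node in t1.root.iter():
        if mapping.has_t1(node):
            continue
        path = xpath_of(node)
        parent_path = xpath_of(node.parent) if node.parent is not None else None
        if node.is_text:
            delta.deletes.append(
                DeltaOperation(
                    "delete",
                    "text",
                    uid(),
                    old_path=path,
                    old_parent=parent_path,
                    old_child_no=node.child_index,
                    old_value=node.text,
                )
            )
        else:
            delta.deletes.append(
                DeltaOperation(
                    "delete",
                    "node",
                    uid(),
                    old_path=path,
                    old_parent=parent_path,
                    old_child_no=node.child_index,
                    old_tag=node.tag,
                )
            )
            for name in sorted(node.attributes):
                delta.deletes.append(
                    DeltaOperation(
                        "delete",
                        "attribute",
                        uid(),
                        old_path=path,
                        attr_name=name,
                        old_value=node.attributes[name],
                    )
                )

    # --- unmapped T2 nodes: inserts
    for node in t2.root.iter():
        if mapping.has_t2(node):
            continue
        path = xpath_of(node)
        parent_path = xpath_of(node.parent) if node.parent is not None else None
        if node.is_text:
            delta.inserts.append(
                DeltaOperation(
                    "insert",
                    "text",
                    uid(),
                    new_path=path,
                    new_parent=parent_path,
                    new_child_no=node.child_index,
                    new_value=node.text,
                )
            )
        else:
            delta.inserts.append(
                DeltaOperation(
                    "insert",
                    "node",
                    uid(),
                    new_path=path,
                    new_parent=parent_path,
                    new_child_no=node.child_index,
                    new_tag=node.tag,
                )
            )
            for name in sorted(node.attributes):
                delta.inserts.append(
                    DeltaOperation(
                        "insert",
                        "attribute",
                        uid(),
                        new_path=path,
                        attr_name=name,
                        new_value=node.attributes[name],
                    )
                )

    # --- moves: parent pair broken, or sibling sequence changed
    moved_t2: list[DocNode] = []
    for m, n in mapping.pairs():
        if m.parent is None or n.parent is None:
            continue
        if mapping.partner_in_t1(n.parent) is not m.parent:
            moved_t2.append(n)
    for m, n in mapping.pairs():
        stay = [
            c
            for c in n.children
            if mapping.partner_in_t1(c) is not None
            and mapping.partner_in_t1(c).parent is m
        ]
        if len(stay) > 1:
            sequence = [mapping.partner_in_t1(c).child_index for c in stay]
            flags = _lis_member_flags(sequence)
            moved_t2.extend(c for c, keep in zip(stay, flags) if not keep)

    for n in sorted(moved_t2, key=lambda node: node.doc_order):
        m = mapping.partner_in_t1(n)
        if n.is_text:
            # moves hold document nodes only: a relocated text pair is
            # expressed as delete + insert of its content
            delta.deletes.append(
                DeltaOperation(
                    "delete",
                    "text",
                    uid(),
                    old_path=xpath_of(m),
                    old_parent=xpath_of(m.parent),
                    old_child_no=m.child_index,
                    old_value=m.text,
                )
            )
            delta.inserts.append(
                DeltaOperation(
                    "insert",
                    "text",
                    uid(),
                    new_path=xpath_of(n),
                    new_parent=xpath_of(n.parent),
                    new_child_no=n.child_index,
                    new_value=n.text,
                )
            )
        else:
            delta.moves.append(
                DeltaOperation(
                    "move",
                    "node",
                    uid(),
                    old_path=xpath_of(m),
                    new_path=xpath_of(n),
                    old_parent=xpath_of(m.parent),
                    new_parent=xpath_of(n.parent),
                    old_child_no=m.child_index,
                    new_child_no=n.child_index,
                )
            )
    moved_text_pairs = {id(n) for n in moved_t2 if n.is_text}

    # --- attribute / text / root-tag changes on mapped pairs
    for m, n in mapping.pairs():
        old_path, new_path = xpath_of(m), xpath_of(n)
        if m is t1.root and n is t2.root and m.tag != n.tag:
            delta.updates.append(
                DeltaOperation(
                    "update",
                    "node",
                    uid(),
                    old_path=old_path,
                    new_path=new_path,
                    old_tag=m.tag,
                    new_tag=n.tag,
                )
            )
        if m.is_text:
            if m.text != n.text and id(n) not in moved_text_pairs:
                delta.updates.append(
                    DeltaOperation(
                        "update",
                        "text",
                        uid(),
                        old_path=old_path,
                        new_path=new_path,
                        old_value=m.text,
                        new_value=n.text,
                    )
                )
            continue
        for name in sorted(set(m.attributes) | set(n.attributes)):
            old = m.attributes.get(name)
            new = n.attributes.get(name)
            if old == new:
                continue
            if new is None:
                delta.deletes.append(
                    DeltaOperation(
                        "delete",
                        "attribute",
                        uid(),
                        old_path=old_path,
                        attr_name=name,
                        old_value=old,
                    )
                )
            elif old is None:
                delta.inserts.append(
                    DeltaOperation(
                        "insert",
                        "attribute",
                        uid(),
                        new_path=new_path,
                        attr_name=name,
                        new_value=new,
                    )
                )
            else:
                delta.updates.append(
                    DeltaOperation(
                        "update",
                        "attribute",
                        uid(),
                        old_path=old_path,
                        new_path=new_path,
                        attr_name=name,
                        old_value=old,
                        new_value=new,
                    )
                )
    return delta


# -- XML dialect -----------------------------------------------------------

_SECTIONS = ("deletes", "inserts", "moves", "updates")
_ATTR_ORDER = (
    ("uid", "id"),
    ("old_path", "oldPath"),
    ("new_path", "newPath"),
    ("old_parent", "oldParent"),
    ("new_parent", "newParent"),
    ("old_child_no", "oldChildNo"),
    ("new_child_no", "newChildNo"),
    ("old_tag", "oldTag"),
    ("new_tag", "newTag"),
    ("attr_name", "name"),
    ("old_value", "oldValue"),
    ("new_value", "newValue"),
)


def serialize_delta(delta: Delta) -> str:
    """Encode a delta as an XML document with four fixed sections.

    Attribute order follows the dialect enumeration, making output
    byte-stable for equal deltas.
    """
    root = etree.Element("diff")
    for section in _SECTIONS:
        holder = etree.SubElement(root, section)
        for op in getattr(delta, section):
            element = etree.SubElement(holder, op.entity_kind)
            for attr, xml_name in _ATTR_ORDER:
                value = getattr(op, attr)
                if value is not None:
                    element.set(xml_name, str(value))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


_KIND_BY_SECTION = {
    "deletes": "delete",
    "inserts": "insert",
    "moves": "move",
    "updates": "update",
}

_REQUIRED_PATHS = {
    "insert": ("new_path",),
    "delete": ("old_path",),
    "move": ("old_path", "new_path"),
    "update": ("old_path", "new_path"),
}


def parse_delta(xml_text) -> Delta:
    """Reconstruct a :class:`Delta` from its XML encoding.

    Unknown sections, unknown entity elements or missing mandatory
    attributes raise :class:`DeltaFormatError` naming the offending element.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    parser = etree.XMLParser(resolve_entities=False, no_network=True, remove_comments=True)
    try:
        root = etree.fromstring(xml_text, parser=parser)
    except etree.XMLSyntaxError as exc:
        raise DeltaFormatError(f"malformed delta document: {exc}") from exc
    if root.tag != "diff":
        raise DeltaFormatError(f"unexpected root element {root.tag!r}")
    delta = Delta()
    for holder in root:
        section = holder.tag
        if section not in _SECTIONS:
            raise DeltaFormatError(f"unknown section {section!r}")
        op_kind = _KIND_BY_SECTION[section]
        for element in holder:
            if element.tag not in ("node", "attribute", "text"):
                raise DeltaFormatError(
                    f"unknown entity element {element.tag!r} in section {section!r}"
                )
            fields = {"op_kind": op_kind, "entity_kind": element.tag}
            for attr, xml_name in _ATTR_ORDER:
                if xml_name in element.attrib:
                    value = element.get(xml_name)
                    if attr in ("old_child_no", "new_child_no"):
                        value = int(value)
                    fields[attr] = value
            op = DeltaOperation(**fields)
            for required in _REQUIRED_PATHS[op_kind]:
                if getattr(op, required) is None:
                    raise DeltaFormatError(
                        f"element id={op.uid!r} in section {section!r} "
                        f"lacks mandatory attribute {dict(_ATTR_ORDER)[required]}"
                    )
            getattr(delta, section).append(op)
    return delta


# -- inversion -------------------------------------------------------------


def _swap(op: DeltaOperation, op_kind: str) -> DeltaOperation:
    return replace(
        op,
        op_kind=op_kind,
        old_path=op.new_path,
        new_path=op.old_path,
        old_parent=op.new_parent,
        new_parent=op.old_parent,
        old_child_no=op.new_child_no,
        new_child_no=op.old_child_no,
        old_tag=op.new_tag,
        new_tag=op.old_tag,
        old_value=op.new_value,
        new_value=op.old_value,
    )


def invert_delta(delta: Delta) -> Delta:
    """The reverse delta: inserts and deletes swap, old/new fields exchange."""
    return Delta(
        deletes=[_swap(op, "delete") for op in delta.inserts],
        inserts=[_swap(op, "insert") for op in delta.deletes],
        moves=[_swap(op, "move") for op in delta.moves],
        updates=[_swap(op, "update") for op in delta.updates],
    )


# -- patching --------------------------------------------------------------


def _resolve(tree: DocTree, path: Optional[str], op: DeltaOperation) -> DocNode:
    if path is None:
        raise PatchError("operation lacks the required path", op.uid)
    try:
        return resolve_path(tree, path)
    except KeyError as exc:
        raise PatchError(f"cannot resolve path {path!r}: {exc}", op.uid) from exc


def patch(tree: DocTree, delta: Delta) -> DocTree:
    """Apply a delta to a document tree, returning the transformed tree.

    The input tree is never modified; a failing operation raises
    :class:`PatchError` (naming the operation id) before any result is
    returned, so partial application is never committed.

    Old-path coordinates refer to the document before the patch, new-path
    coordinates to the document after it.  Deletions and move-detachments
    are resolved against the pre-patch tree up front; moves and inserts are
    then attached in ascending destination depth and child number, which
    guarantees every destination parent exists when needed.
    """
    work = tree.copy()

    # resolve everything addressed in pre-patch coordinates first
    node_deletes = [
        (op, _resolve(work, op.old_path, op))
        for op in delta.deletes
        if op.entity_kind in ("node", "text")
    ]
    attr_deletes = [
        (op, _resolve(work, op.old_path, op))
        for op in delta.deletes
        if op.entity_kind == "attribute"
    ]
    move_sources = [(op, _resolve(work, op.old_path, op)) for op in delta.moves]
    updates_resolved = []
    for op in delta.updates:
        if op.entity_kind == "node":  # root tag rename
            target = _resolve(work, op.old_path, op)
            if target is not work.root:
                raise PatchError("tag updates are only supported for the root", op.uid)
            updates_resolved.append((op, target))
        else:
            updates_resolved.append((op, _resolve(work, op.old_path, op)))

    # value-level changes (independent of structure)
    for op, node in attr_deletes:
        if op.attr_name is None or op.attr_name not in node.attributes:
            raise PatchError(f"attribute {op.attr_name!r} not present", op.uid)
        del node.attributes[op.attr_name]
    for op, node in updates_resolved:
        if op.entity_kind == "attribute":
            if op.attr_name is None or op.attr_name not in node.attributes:
                raise PatchError(f"attribute {op.attr_name!r} not present", op.uid)
            node.attributes[op.attr_name] = op.new_value or ""
        elif op.entity_kind == "text":
            if not node.is_text:
                raise PatchError("text update does not address a text node", op.uid)
            node.text = op.new_value or ""
        else:
            node.tag = op.new_tag or node.tag

    # structural phase: detach, then attach in destination order
    for op, node in sorted(
        node_deletes, key=lambda item: item[1].depth, reverse=True
    ):
        if node.parent is None:
            raise PatchError("cannot delete the document root", op.uid)
        node.detach()
    for op, node in move_sources:
        if node.parent is None:
            raise PatchError("cannot move the document root", op.uid)
        node.detach()

    additions: list[tuple[int, int, str, DeltaOperation, Optional[DocNode]]] = []
    for op, node in move_sources:
        additions.append((_path_depth(op.new_path), op.new_child_no or 1, "move", op, node))
    for op in delta.inserts:
        if op.entity_kind != "attribute":
            additions.append(
                (_path_depth(op.new_path), op.new_child_no or 1, "insert", op, None)
            )
    additions.sort(key=lambda item: (item[0], item[1], item[2]))
    for _, child_no, kind, op, node in additions:
        parent = _resolve(work, op.new_parent, op)
        if node is None:
            if op.entity_kind == "text":
                node = DocNode(text=op.new_value or "")
            else:
                if op.new_tag is None:
                    raise PatchError("node insert lacks newTag", op.uid)
                node = DocNode(tag=op.new_tag)
        index = min(max(child_no - 1, 0), len(parent.children))
        parent.insert(index, node)

    # attribute inserts address post-patch coordinates
    for op in delta.inserts:
        if op.entity_kind == "attribute":
            target = _resolve(work, op.new_path, op)
            if op.attr_name is None:
                raise PatchError("attribute insert lacks a name", op.uid)
            target.attributes[op.attr_name] = op.new_value or ""

    return work.reindex()


def _path_depth(path: Optional[str]) -> int:
    return 0 if path is None else path.count("/")
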