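"""Human-readable change reports (Markdown, ReStructuredText, HTML).

The report lists the entities that matter to the biological model — species,
parameters, reactions, compartments, events and so on — together with what
happened to each (inserted, deleted, moved, attribute changed, math
changed).  Operations that do not touch a model-relevant entity are
omitted.  All three output formats carry the same set of change lines, only
the markup differs.
"""

from __future__ import annotations

import html
from dataclasses import dataclass

from .delta import Delta
from .xmltree import DocNode, DocTree, resolve_path

__all__ = ["generate_report", "collect_changes", "ChangeRecord", "REPORT_FORMATS"]

REPORT_FORMATS = ("markdown", "rst", "html")

# entities worth reporting, per dialect; generic documents report every element
RELEVANT_TAGS = {
    "sbml": frozenset(
        {
            "species",
            "parameter",
            "localParameter",
            "reaction",
            "compartment",
            "rule",
            "assignmentRule",
            "rateRule",
            "algebraicRule",
            "event",
            "functionDefinition",
            "unitDefinition",
        }
    ),
    "cellml": frozenset({"component", "variable", "reaction", "connection", "units"}),
}


@dataclass(frozen=True)
class ChangeRecord:
    entity_kind: str
    entity_label: str
    action: str
    detail: str = ""

    @property
    def line(self) -> str:
        text = f"{self.action} {self.entity_kind} '{self.entity_label}'"
        if self.detail:
            text += f": {self.detail}"
        return text


def _display_name(node: DocNode) -> str:
    from .xmltree import xpath_of

    for attr in ("name", "id"):
        for key, value in node.attributes.items():
            if key.split("}")[-1] == attr:
                return value
    return xpath_of(node)


def _owning_entity(node: DocNode, relevant) -> DocNode | None:
    current = node
    while current is not None:
        if not current.is_text and (relevant is None or current.local_name in relevant):
            return current
        current = current.parent
    return None


def _inside_math(node: DocNode) -> bool:
    current = node
    while current is not None:
        if not current.is_text and current.local_name == "math":
            return True
        current = current.parent
    return False


def _safe_resolve(tree: DocTree, path: str | None) -> DocNode | None:
    if path is None:
        return None
    try:
        return resolve_path(tree, path)
    except KeyError:
        return None


def collect_changes(delta: Delta, t1: DocTree, t2: DocTree, dialect: str) -> list[ChangeRecord]:
    """Distil the delta into one record per model-relevant change."""
    relevant = RELEVANT_TAGS.get(dialect)  # None -> report everything
    records: list[ChangeRecord] = []
    seen: set[tuple] = set()

    def emit(record: ChangeRecord, key: tuple) -> None:
        if key not in seen:
            seen.add(key)
            records.append(record)

    def node_change(tree: DocTree, path: str | None, action: str) -> None:
        node = _safe_resolve(tree, path)
        if node is None or node.is_text:
            return
        owner = _owning_entity(node, relevant)
        if owner is None:
            return
        if owner is not node and action in ("inserted", "deleted"):
            # a structural change inside an entity that is itself inserted or
            # deleted is part of that entity's own record
            from .xmltree import xpath_of

            if xpath_of(owner) in _node_paths(delta, "insert" if action == "inserted" else "delete"):
                return
        if _inside_math(node) or owner is not node:
            if _inside_math(node):
                emit(
                    ChangeRecord(owner.local_name, _display_name(owner), "updated", "math changed"),
                    ("math", id(owner)),
                )
            else:
                emit(
                    ChangeRecord(
                        owner.local_name,
                        _display_name(owner),
                        "updated",
                        f"{action} {node.local_name}",
                    ),
                    ("part", id(owner), action, node.local_name),
                )
        else:
            emit(
                ChangeRecord(owner.local_name, _display_name(owner), action),
                (action, id(owner)),
            )

    for op in delta.deletes:
        if op.entity_kind == "node":
            node_change(t1, op.old_path, "deleted")
        elif op.entity_kind == "attribute":
            node = _safe_resolve(t1, op.old_path)
            if node is None or not _is_mapped_side(node, t1, t2, delta):
                continue  # attributes of deleted nodes fold into the node record
            owner = _owning_entity(node, relevant)
            if owner is not None:
                emit(
                    ChangeRecord(
                        owner.local_name,
                        _display_name(owner),
                        "updated",
                        f"attribute {op.attr_name} removed (was '{op.old_value}')",
                    ),
                    ("attr-del", id(owner), op.attr_name),
                )
    for op in delta.inserts:
        if op.entity_kind == "node":
            node_change(t2, op.new_path, "inserted")
        elif op.entity_kind == "attribute":
            node = _safe_resolve(t2, op.new_path)
            if node is None or not _is_mapped_side(node, t2, t1, delta, inserted=True):
                continue
            owner = _owning_entity(node, relevant)
            if owner is not None:
                emit(
                    ChangeRecord(
                        owner.local_name,
                        _display_name(owner),
                        "updated",
                        f"attribute {op.attr_name} added ('{op.new_value}')",
                    ),
                    ("attr-ins", id(owner), op.attr_name),
                )
    for op in delta.moves:
        node_change(t2, op.new_path, "moved")
    for op in delta.updates:
        if op.entity_kind == "attribute":
            node = _safe_resolve(t1, op.old_path)
            if node is None:
                continue
            owner = _owning_entity(node, relevant)
            if owner is None:
                continue
            emit(
                ChangeRecord(
                    owner.local_name,
                    _display_name(owner),
                    "updated",
                    f"attribute {op.attr_name} changed from '{op.old_value}' to '{op.new_value}'",
                ),
                ("attr-upd", id(owner), op.attr_name),
            )
        elif op.entity_kind == "text":
            node = _safe_resolve(t1, op.old_path)
            if node is None:
                continue
            owner = _owning_entity(node, relevant)
            if owner is None:
                continue
            detail = "math changed" if _inside_math(node) else "text changed"
            emit(
                ChangeRecord(owner.local_name, _display_name(owner), "updated", detail),
                ("text", id(owner), detail),
            )
        else:  # root tag rename
            emit(
                ChangeRecord(
                    "document",
                    op.old_tag or "",
                    "updated",
                    f"root tag renamed to '{op.new_tag}'",
                ),
                ("root-tag",),
            )
    return records


def _node_paths(delta: Delta, kind: str) -> set[str]:
    ops = delta.deletes if kind == "delete" else delta.inserts
    return {
        (op.old_path if kind == "delete" else op.new_path)
        for op in ops
        if op.entity_kind in ("node", "text")
    }


def _is_mapped_side(node, tree, other, delta, inserted: bool = False) -> bool:
    # an attribute op on a node that is itself inserted/deleted is part of
    # that node's own record, not a separate change
    from .xmltree import xpath_of

    paths = _node_paths(delta, "insert" if inserted else "delete")
    return xpath_of(node) not in paths


# -- rendering -------------------------------------------------------------

_HEADINGS = {"deleted": "Deleted", "inserted": "Inserted", "moved": "Moved", "updated": "Updated"}


def generate_report(delta: Delta, t1: DocTree, t2: DocTree, format: str = "markdown", dialect: str | None = None) -> str:
    """Render the change report in one of ``markdown``, ``rst`` or ``html``."""
    if dialect is None:
        from .domainrules import detect_dialect

        dialect = detect_dialect(t1)
        if dialect == "generic":
            dialect = detect_dialect(t2)
    if format not in REPORT_FORMATS:
        raise ValueError(
            f"unknown report format {format!r}; expected one of {', '.join(REPORT_FORMATS)}"
        )
    records = collect_changes(delta, t1, t2, dialect)
    title = "Model differences"
    if not records:
        body = "No differences were found."
        if format == "markdown":
            return f"# {title}\n\n{body}\n"
        if format == "rst":
            return f"{title}\n{'=' * len(title)}\n\n{body}\n"
        return (
            f"<div class='modeldiff-report'><h1>{title}</h1>"
            f"<p>{body}</p></div>\n"
        )
    lines = [record.line for record in records]
    if format == "markdown":
        out = [f"# {title}", ""]
        out += [f"- {line}" for line in lines]
        return "\n".join(out) + "\n"
    if format == "rst":
        out = [title, "=" * len(title), ""]
        out += [f"- {line}" for line in lines]
        return "\n".join(out) + "\n"
    items = "".join(f"<li>{html.escape(line)}</li>" for line in lines)
    return (
        f"<div class='modeldiff-report'><h1>{title}</h1>"
        f"<ul>{items}</ul></div>\n"
    )
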