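"""High-level diff driver tying the pipeline together."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .delta import Delta, compute_delta
from .domainrules import apply_domain_rules, detect_dialect
from .mapping import (
    NodeMapping,
    default_chase_depth,
    map_by_id,
    optimize,
    propagate_bottom_up,
    propagate_top_down,
)
from .xmltree import DocTree, parse_document

__all__ = ["DiffResult", "diff_trees", "diff"]


@dataclass
class DiffResult:
    """Everything produced by one comparison run."""

    t1: DocTree
    t2: DocTree
    mapping: NodeMapping
    delta: Delta
    dialect: str
    matrices: list = field(default_factory=list)
    phase_stats: list = field(default_factory=list)  # (phase, pairs, seconds)


def diff_trees(
    t1: DocTree,
    t2: DocTree,
    domain_rules: bool = True,
    chase_depth=default_chase_depth,
) -> DiffResult:
    """Map two parsed trees, post-process, and derive the delta.

    Phase order is fixed: by-id, bottom-up, top-down (signatures),
    optimization, then dialect glue rules (unless ``domain_rules`` is off).
    """
    dialect = detect_dialect(t1)
    if dialect == "generic":
        dialect = detect_dialect(t2)
    mapping = NodeMapping()
    mapping.add(t1.root, t2.root)
    matrices: list = []
    stats: list = []

    def timed(name, fn, *args, **kwargs):
        before = len(mapping)
        start = time.perf_counter()
        fn(*args, **kwargs)
        stats.append((name, len(mapping) - before, time.perf_counter() - start))

    timed("map_by_id", map_by_id, t1, t2, mapping)
    timed("bottom_up", propagate_bottom_up, t1, t2, mapping)
    timed("top_down", propagate_top_down, t1, t2, mapping, chase_depth=chase_depth)
    timed("optimize", optimize, t1, t2, mapping, trace=matrices)
    if domain_rules:
        timed("domain_rules", apply_domain_rules, dialect, mapping)
    delta = compute_delta(t1, t2, mapping)
    return DiffResult(
        t1=t1,
        t2=t2,
        mapping=mapping,
        delta=delta,
        dialect=dialect,
        matrices=matrices,
        phase_stats=stats,
    )


def diff(xml1, xml2, domain_rules: bool = True) -> DiffResult:
    """Parse two XML texts and compare them."""
    return diff_trees(parse_document(xml1), parse_document(xml2), domain_rules=domain_rules)
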