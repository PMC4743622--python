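"""Node correspondence between two document trees (bottom-up / lazy-down matching).

Four phases, run in a fixed order:

1. **by id** — nodes sharing a biological identifier (annotation URI) are
   paired first, then nodes sharing an ``id`` attribute value;
2. **bottom-up propagation** — mapped children suggest their partners'
   parents, weighted by subtree size;
3. **top-down propagation** — a max-weight priority queue over the second
   tree finds identical subtrees by signature and pairs them wholesale,
   together with the intervening ancestors;
4. **optimization** — unmatched children of every mapped pair are compared
   through an attribute-distance matrix and greedily paired up to a maximum
   distance of 0.9.

The mapping is injective in both directions and the roots of the two trees
are always paired (the only pair allowed to differ in tag name).
"""

from __future__ import annotations

import heapq
import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

from .xmltree import DocNode, DocTree

__all__ = [
    "NodeMapping",
    "DistanceMatrix",
    "CandidateSuggestion",
    "map_by_id",
    "propagate_bottom_up",
    "propagate_top_down",
    "optimize",
    "compute_mapping",
    "default_chase_depth",
    "OPTIMIZE_MAX_DISTANCE",
]

INF = math.inf

#: inclusive distance threshold of the optimization phase
OPTIMIZE_MAX_DISTANCE = 0.9

#: substrings identifying biological-identifier URIs in annotation subtrees
BIO_ID_PATTERNS = (
    re.compile(r"identifiers\.org/\S+"),
    re.compile(r"urn:miriam:\S+"),
)


class MappingError(RuntimeError):
    pass


class NodeMapping:
    """Injective bidirectional correspondence between nodes of T1 and T2."""

    def __init__(self) -> None:
        self._t1_to_t2: dict[int, DocNode] = {}
        self._t2_to_t1: dict[int, DocNode] = {}
        self._pairs: dict[int, tuple[DocNode, DocNode]] = {}

    def __len__(self) -> int:
        return len(self._pairs)

    def pairs(self) -> Iterator[tuple[DocNode, DocNode]]:
        """(node-in-T1, node-in-T2) pairs in insertion order."""
        yield from self._pairs.values()

    def add(self, n1: DocNode, n2: DocNode) -> None:
        if id(n1) in self._t1_to_t2 or id(n2) in self._t2_to_t1:
            raise MappingError("node already participates in a pair")
        self._t1_to_t2[id(n1)] = n2
        self._t2_to_t1[id(n2)] = n1
        self._pairs[id(n1)] = (n1, n2)

    def remove(self, n1: DocNode) -> None:
        n2 = self._t1_to_t2.pop(id(n1))
        del self._t2_to_t1[id(n2)]
        del self._pairs[id(n1)]

    def partner_in_t2(self, n1: DocNode) -> Optional[DocNode]:
        return self._t1_to_t2.get(id(n1))

    def partner_in_t1(self, n2: DocNode) -> Optional[DocNode]:
        return self._t2_to_t1.get(id(n2))

    def has_t1(self, n1: DocNode) -> bool:
        return id(n1) in self._t1_to_t2

    def has_t2(self, n2: DocNode) -> bool:
        return id(n2) in self._t2_to_t1

    def are_paired(self, n1: DocNode, n2: DocNode) -> bool:
        return self._t1_to_t2.get(id(n1)) is n2

    def copy(self) -> "NodeMapping":
        dup = NodeMapping()
        for n1, n2 in self.pairs():
            dup.add(n1, n2)
        return dup


@dataclass
class CandidateSuggestion:
    """A T1 candidate parent suggested during bottom-up propagation."""

    candidate: DocNode
    confidence: float  # summed weights of the suggesting children, > 0


@dataclass
class DistanceMatrix:
    """Attribute-distance matrix over the unmatched children of a mapped pair.

    Rows index unmatched children of the T2 node, columns unmatched children
    of the T1 node.  Entries lie in [0, 1] or are ``inf`` when the two child
    nodes cannot be paired (different tags).
    """

    t1_parent: DocNode
    t2_parent: DocNode
    row_nodes: list = field(default_factory=list)  # children of the T2 node
    col_nodes: list = field(default_factory=list)  # children of the T1 node
    values: list = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_nodes), len(self.col_nodes))


# -- phase 1: by id --------------------------------------------------------


def _harvest_bio_ids(tree: DocTree) -> dict[str, DocNode]:
    """URI -> annotated entity, for URIs occurring exactly once in the tree.

    Biological identifiers are attribute values inside ``annotation``
    subtrees whose value matches an identifier-URI pattern; the annotated
    entity is the parent of the annotation element.
    """
    found: dict[str, list[DocNode]] = {}
    for node in tree.nodes:
        if node.is_text or node.local_name != "annotation" or node.parent is None:
            continue
        owner = node.parent
        for sub in node.iter():
            for value in sub.attributes.values():
                if any(p.search(value) for p in BIO_ID_PATTERNS):
                    owners = found.setdefault(value, [])
                    if owner not in owners:
                        owners.append(owner)
    return {uri: owners[0] for uri, owners in found.items() if len(owners) == 1}


def map_by_id(t1: DocTree, t2: DocTree, mapping: NodeMapping) -> NodeMapping:
    """Pair nodes sharing a biological identifier, then nodes sharing an id.

    Biological identifiers take priority over plain ``id`` attributes.
    Existing pairs are never overwritten; tags must agree.
    """
    bio1, bio2 = _harvest_bio_ids(t1), _harvest_bio_ids(t2)
    for uri in bio1.keys() & bio2.keys():
        n1, n2 = bio1[uri], bio2[uri]
        if n1.tag == n2.tag and not mapping.has_t1(n1) and not mapping.has_t2(n2):
            mapping.add(n1, n2)
    for ident, n1 in t1.id_index.items():
        n2 = t2.id_index.get(ident)
        if n2 is None or n1.tag != n2.tag:
            continue
        if not mapping.has_t1(n1) and not mapping.has_t2(n2):
            mapping.add(n1, n2)
    return mapping


# -- phase 2: bottom-up propagation ---------------------------------------


def propagate_bottom_up(t1: DocTree, t2: DocTree, mapping: NodeMapping) -> NodeMapping:
    """Propagate the mapping upwards: mapped children suggest their partners'
    parents with confidence equal to the child's weight; an unconnected node
    adopts the unconnected same-tag candidate with the highest summed
    confidence (ties broken by T1 document order)."""
    for n in t2.root.iter_postorder():
        if n.is_text or mapping.has_t2(n):
            continue
        confidence: dict[int, CandidateSuggestion] = {}
        for child in n.children:
            partner = mapping.partner_in_t1(child)
            if partner is None or partner.parent is None:
                continue
            cand = partner.parent
            entry = confidence.get(id(cand))
            if entry is None:
                confidence[id(cand)] = CandidateSuggestion(cand, child.weight)
            else:
                entry.confidence += child.weight
        best = None
        for sug in sorted(
            confidence.values(),
            key=lambda s: (-s.confidence, s.candidate.doc_order),
        ):
            if sug.candidate.tag != n.tag:  # different tag name: neglected
                continue
            if mapping.has_t1(sug.candidate):  # already connected: neglected
                continue
            best = sug.candidate
            break
        if best is not None:
            mapping.add(best, n)
    return mapping


# -- phase 3: top-down propagation ----------------------------------------


def default_chase_depth(weight: float, root_weight: float, height: int) -> int:
    """How many ancestor levels to climb when anchoring a signature match.

    Grows with the ratio of the subtree weight to the whole-document weight:
    leaves look only a couple of levels up, large subtrees may climb to the
    root.  At least the parent and grandparent are always examined.
    """
    if root_weight <= 0:
        return 1
    return 1 + math.ceil((weight / root_weight) * max(height, 1))


def _map_identical_subtrees(m: DocNode, n: DocNode, mapping: NodeMapping) -> None:
    # equal signatures: identical structure, pair corresponding nodes
    if not mapping.has_t1(m) and not mapping.has_t2(n):
        mapping.add(m, n)
    for cm, cn in zip(m.children, n.children):
        _map_identical_subtrees(cm, cn, mapping)


def _ancestors_within(node: DocNode, depth: int) -> list[DocNode]:
    out = []
    current = node.parent
    while current is not None and len(out) < depth:
        out.append(current)
        current = current.parent
    return out


def propagate_top_down(
    t1: DocTree,
    t2: DocTree,
    mapping: NodeMapping,
    chase_depth: Callable[[float, float, int], int] = default_chase_depth,
) -> NodeMapping:
    """Pair identical subtrees found via signatures, largest first.

    A priority queue over T2 (max weight first, ties by document order) is
    processed: for the heaviest node n, unmapped T1 nodes with n's signature
    are candidates; a candidate qualifies when one of its ancestors is
    already paired with an ancestor of n within the chase depth.  The
    qualifying candidate with the nearest such ancestor wins; both subtrees
    are then paired node by node, as are the unpaired same-tag ancestors up
    to the discovered pairing.
    """
    root_weight = t2.root_weight
    height = t2.height
    counter = 0
    heap: list[tuple[float, int, DocNode]] = []

    def push(node: DocNode) -> None:
        nonlocal counter
        heapq.heappush(heap, (-node.weight, node.doc_order, node))
        counter += 1

    def push_children(node: DocNode) -> None:
        for child in node.children:
            push(child)

    push(t2.root)
    while heap:
        _, _, n = heapq.heappop(heap)
        m = mapping.partner_in_t1(n)
        if m is not None:
            if m.signature == n.signature:
                _map_identical_subtrees(m, n, mapping)
            else:
                push_children(n)
            continue
        candidates = [
            c for c in t1.signature_index.get(n.signature, []) if not mapping.has_t1(c)
        ]
        if not candidates:
            push_children(n)
            continue
        depth = max(1, chase_depth(n.weight, root_weight, height))
        n_ancestors = _ancestors_within(n, depth)
        best: Optional[tuple[int, int, DocNode, DocNode, DocNode]] = None
        for cand in candidates:
            for dist, a_m in enumerate(_ancestors_within(cand, depth), start=1):
                a_n = mapping.partner_in_t2(a_m)
                if a_n is not None and a_n in n_ancestors:
                    key = (dist, cand.doc_order)
                    if best is None or key < (best[0], best[1]):
                        best = (dist, cand.doc_order, cand, a_m, a_n)
                    break
        if best is None:
            push_children(n)
            continue
        _, _, m, anchor_m, anchor_n = best
        _map_identical_subtrees(m, n, mapping)
        # pair the ancestors up to the discovered pairing
        u, v = n.parent, m.parent
        while u is not None and v is not None and u is not anchor_n and v is not anchor_m:
            if mapping.has_t2(u) or mapping.has_t1(v) or u.tag != v.tag:
                break
            mapping.add(v, u)
            u, v = u.parent, v.parent
    return mapping


# -- phase 4: optimization -------------------------------------------------


def _attribute_distance(c1: DocNode, c2: DocNode) -> float:
    """Share of differing attributes among the union of attribute names.

    0 when both nodes carry no attributes; an attribute differs when it is
    absent on one side or its values disagree.
    """
    names = set(c1.attributes) | set(c2.attributes)
    if not names:
        return 0.0
    differing = sum(
        1 for name in names if c1.attributes.get(name) != c2.attributes.get(name)
    )
    return differing / len(names)


def build_distance_matrix(
    m: DocNode, n: DocNode, mapping: NodeMapping
) -> Optional[DistanceMatrix]:
    """Distance matrix over the unmatched children of the mapped pair (m, n)."""
    un1 = [c for c in m.children if not mapping.has_t1(c)]
    un2 = [c for c in n.children if not mapping.has_t2(c)]
    if not un1 or not un2:
        return None
    matrix = DistanceMatrix(t1_parent=m, t2_parent=n, row_nodes=un2, col_nodes=un1)
    for row in un2:
        matrix.values.append(
            [
                _attribute_distance(col, row) if col.tag == row.tag else INF
                for col in un1
            ]
        )
    return matrix


def optimize(
    t1: DocTree,
    t2: DocTree,
    mapping: NodeMapping,
    max_distance: float = OPTIMIZE_MAX_DISTANCE,
    trace: Optional[list] = None,
) -> NodeMapping:
    """Pair unmatched children of mapped pairs, greedily by attribute distance.

    The sweep visits mapped pairs top-down in T2 document order, so children
    of pairs added earlier in the sweep are themselves processed.  Within one
    matrix, candidate pairs are taken in strictly ascending distance
    (row-major tie-break) while the distance stays ≤ ``max_distance``.
    """
    for n in t2.root.iter():
        m = mapping.partner_in_t1(n)
        if m is None:
            continue
        matrix = build_distance_matrix(m, n, mapping)
        if matrix is None:
            continue
        if trace is not None:
            trace.append(matrix)
        entries = [
            (matrix.values[i][j], i, j)
            for i in range(len(matrix.row_nodes))
            for j in range(len(matrix.col_nodes))
        ]
        used_rows: set[int] = set()
        used_cols: set[int] = set()
        for dist, i, j in sorted(entries, key=lambda e: (e[0], e[1], e[2])):
            if dist > max_distance:
                break
            if i in used_rows or j in used_cols:
                continue
            mapping.add(matrix.col_nodes[j], matrix.row_nodes[i])
            used_rows.add(i)
            used_cols.add(j)
    return mapping


# -- driver ----------------------------------------------------------------


def compute_mapping(
    t1: DocTree,
    t2: DocTree,
    trace: Optional[list] = None,
    chase_depth: Callable[[float, float, int], int] = default_chase_depth,
) -> NodeMapping:
    """Run the four matching phases in order and return the final mapping.

    The two roots are paired up front (they always correspond, even when
    their tag names differ).  ``trace``, when given, collects the
    :class:`DistanceMatrix` instances built during optimization.
    """
    mapping = NodeMapping()
    mapping.add(t1.root, t2.root)
    map_by_id(t1, t2, mapping)
    propagate_bottom_up(t1, t2, mapping)
    propagate_top_down(t1, t2, mapping, chase_depth=chase_depth)
    optimize(t1, t2, mapping, trace=trace)
    return mapping
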