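"""The four matching phases and their invariants."""

import pytest
from hypothesis import given, strategies as st

from conftest import random_generic_xml
from modeldiff.fixtures import make_fig2_pair, mutate, random_model
from modeldiff.mapping import (
    NodeMapping,
    build_distance_matrix,
    compute_mapping,
    map_by_id,
    optimize,
    propagate_bottom_up,
    propagate_top_down,
)
from modeldiff.xmltree import parse_document


def by_local_name(tree, name):
    return [n for n in tree.nodes if not n.is_text and n.local_name == name]


class TestMapById:
    def test_shared_id_attribute_pairs_nodes(self, fig2_trees):
        t1, t2 = fig2_trees
        mapping = map_by_id(t1, t2, NodeMapping())
        (r1,), (r2,) = by_local_name(t1, "reaction"), by_local_name(t2, "reaction")
        assert mapping.are_paired(r1, r2)
        assert len(mapping) == 1  # only the reaction ids coincide

    def test_biological_identifier_outranks_id_attribute(self):
        uri = "http://identifiers.org/chebi/CHEBI:17234"
        v1 = f'<sbml><species id="x"><annotation><link resource="{uri}"/></annotation></species></sbml>'
        v2 = (
            f'<sbml><species id="y"><annotation><link resource="{uri}"/></annotation></species>'
            '<species id="x"/></sbml>'
        )
        t1, t2 = parse_document(v1), parse_document(v2)
        mapping = map_by_id(t1, t2, NodeMapping())
        annotated_v2 = t2.root.children[0]
        assert mapping.partner_in_t1(annotated_v2) is t1.root.children[0]
        # the same-id decoy stayed unmapped: URI pairing claimed the T1 node first
        assert not mapping.has_t2(t2.root.children[1])

    def test_no_shared_identifiers_leaves_mapping_unchanged(self):
        t1 = parse_document('<r><a id="p"/></r>')
        t2 = parse_document('<r><a id="q"/></r>')
        assert len(map_by_id(t1, t2, NodeMapping())) == 0

    def test_existing_pairs_are_never_overwritten(self):
        t1 = parse_document('<r><a id="x"/><b/></r>')
        t2 = parse_document('<r><a id="x"/></r>')
        mapping = NodeMapping()
        mapping.add(t1.root.children[0], t2.root.children[0])
        map_by_id(t1, t2, mapping)
        assert len(mapping) == 1


class TestBottomUp:
    def test_mapped_child_pulls_ancestor_chain_upwards(self, fig2_trees):
        t1, t2 = fig2_trees
        mapping = map_by_id(t1, t2, NodeMapping())
        propagate_bottom_up(t1, t2, mapping)
        (f1,), (f2,) = by_local_name(t1, "listOfReactions"), by_local_name(t2, "listOfReactions")
        assert mapping.are_paired(f1, f2)
        assert mapping.are_paired(t1.root, t2.root)

    def test_candidate_with_different_tag_is_never_adopted(self):
        t1 = parse_document('<r><holderA><x id="i"/></holderA></r>')
        t2 = parse_document('<r><holderB><x id="i"/></holderB></r>')
        mapping = map_by_id(t1, t2, NodeMapping())
        propagate_bottom_up(t1, t2, mapping)
        assert not mapping.has_t2(t2.root.children[0])

    def test_already_connected_candidate_is_never_adopted(self):
        # both T2 containers suggest the single T1 container; only one wins
        t1 = parse_document('<r><c><x id="i"/><y id="j"/></c></r>')
        t2 = parse_document('<r><c><x id="i"/></c><c><y id="j"/></c></r>')
        mapping = map_by_id(t1, t2, NodeMapping())
        propagate_bottom_up(t1, t2, mapping)
        partners = [mapping.has_t2(c) for c in t2.root.children]
        assert partners == [True, False]


class TestTopDown:
    def test_signature_match_pairs_subtrees_and_bridging_ancestors(self, fig2_trees):
        t1, t2 = fig2_trees
        mapping = NodeMapping()
        mapping.add(t1.root, t2.root)
        map_by_id(t1, t2, mapping)
        propagate_bottom_up(t1, t2, mapping)
        propagate_top_down(t1, t2, mapping)
        d1 = next(n for n in by_local_name(t1, "species") if n.attributes.get("name") == "D")
        d2 = next(n for n in by_local_name(t2, "species") if n.attributes.get("name") == "D")
        assert mapping.are_paired(d1, d2)
        (b1,), (b2,) = by_local_name(t1, "listOfSpecies"), by_local_name(t2, "listOfSpecies")
        assert mapping.are_paired(b1, b2)

    @given(st.integers(0, 2000))
    def test_identical_documents_become_fully_paired(self, seed):
        xml = random_generic_xml(seed)
        t1, t2 = parse_document(xml), parse_document(xml)
        mapping = NodeMapping()
        mapping.add(t1.root, t2.root)
        propagate_top_down(t1, t2, mapping)
        assert len(mapping) == len(t2.nodes)

    def test_unmatched_signature_enqueues_children(self):
        # no signature in common except a deep leaf; phase terminates and
        # still discovers the leaf through its parent anchoring
        t1 = parse_document('<r><a q="1"><x id="k"/><same/></a></r>')
        t2 = parse_document('<r><a q="2"><x id="k"/><same/></a></r>')
        mapping = NodeMapping()
        mapping.add(t1.root, t2.root)
        map_by_id(t1, t2, mapping)
        propagate_bottom_up(t1, t2, mapping)
        propagate_top_down(t1, t2, mapping)
        same2 = t2.root.children[0].children[1]
        assert mapping.has_t2(same2)


class TestOptimization:
    def test_attribute_less_same_tag_children_have_distance_zero(self):
        t1 = parse_document("<r><p><c/></p></r>")
        t2 = parse_document("<r><p><c/></p></r>")
        mapping = NodeMapping()
        mapping.add(t1.root, t2.root)
        optimize(t1, t2, mapping)
        assert mapping.are_paired(t1.root.children[0], t2.root.children[0])
        assert mapping.are_paired(
            t1.root.children[0].children[0], t2.root.children[0].children[0]
        )

    def test_disjoint_attribute_sets_give_distance_one_and_no_pair(self):
        t1 = parse_document('<r><c a="1" b="2"/></r>')
        t2 = parse_document('<r><c x="1" y="2"/></r>')
        mapping = NodeMapping()
        mapping.add(t1.root, t2.root)
        matrix = build_distance_matrix(t1.root, t2.root, mapping)
        assert matrix.values == [[1.0]]
        optimize(t1, t2, mapping)
        assert len(mapping) == 1

    def test_threshold_is_inclusive_at_0_9(self):
        # 9 of 10 attributes differ -> distance exactly 0.9 -> still paired
        same = 'k="same"'
        nine_a = " ".join(f'a{i}="{i}"' for i in range(9))
        nine_b = " ".join(f'a{i}="x{i}"' for i in range(9))
        t1 = parse_document(f"<r><c {same} {nine_a}/></r>")
        t2 = parse_document(f"<r><c {same} {nine_b}/></r>")
        mapping = NodeMapping()
        mapping.add(t1.root, t2.root)
        optimize(t1, t2, mapping)
        assert mapping.are_paired(t1.root.children[0], t2.root.children[0])

    def test_distance_above_threshold_is_rejected(self):
        ten_a = " ".join(f'a{i}="{i}"' for i in range(10))
        ten_b = " ".join(f'a{i}="x{i}"' for i in range(10))
        t1 = parse_document(f"<r><c {ten_a}/></r>")
        t2 = parse_document(f"<r><c {ten_b}/></r>")
        mapping = NodeMapping()
        mapping.add(t1.root, t2.root)
        optimize(t1, t2, mapping)
        assert len(mapping) == 1

    def test_different_tags_are_never_compared(self):
        t1 = parse_document("<r><a/></r>")
        t2 = parse_document("<r><b/></r>")
        mapping = NodeMapping()
        mapping.add(t1.root, t2.root)
        matrix = build_distance_matrix(t1.root, t2.root, mapping)
        assert matrix.values == [[float("inf")]]


class TestMappingInvariants:
    @given(st.integers(0, 40))
    def test_injectivity_holds_after_every_phase(self, seed):
        doc = random_model(seed, n_species=4, n_reactions=2)
        mutant, _ = mutate(doc, seed + 7, n_edits=4)
        t1, t2 = parse_document(doc), parse_document(mutant)
        mapping = NodeMapping()
        mapping.add(t1.root, t2.root)
        for phase in (map_by_id, propagate_bottom_up, propagate_top_down, optimize):
            phase(t1, t2, mapping)
            seen1, seen2 = set(), set()
            for n1, n2 in mapping.pairs():
                assert id(n1) not in seen1 and id(n2) not in seen2
                seen1.add(id(n1))
                seen2.add(id(n2))
                if n1.parent is not None:  # only the root pair may rename
                    assert n1.tag == n2.tag

    def test_diff_of_document_with_itself_pairs_every_node(self):
        xml = random_model(3, n_species=4, n_reactions=2)
        t1, t2 = parse_document(xml), parse_document(xml)
        mapping = compute_mapping(t1, t2)
        assert len(mapping) == len(t1.nodes) == len(t2.nodes)

    def test_phases_are_idempotent_on_a_stable_mapping(self):
        v1, v2 = make_fig2_pair()
        t1, t2 = parse_document(v1), parse_document(v2)
        mapping = compute_mapping(t1, t2)
        size = len(mapping)
        for phase in (map_by_id, propagate_bottom_up, propagate_top_down, optimize):
            phase(t1, t2, mapping)
            assert len(mapping) == size
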