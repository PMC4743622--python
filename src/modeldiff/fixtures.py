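"""Deterministic synthetic model documents and ground-truth edit scripts.

Every generator is a pure function of its seed, so tests and the
command-line demo never depend on downloads.  Three entry points:

* :func:`make_fig2_pair` — the minimal worked-example pair: version 1
  encodes the reaction C+D⇄E, version 2 the reaction D+H⇄E with the
  concentration of E changed (species carry no id attributes, only the
  reaction does, which exercises every mapping phase);
* :func:`random_model` — a toy but schema-shaped SBML document with the
  requested numbers of species and reactions;
* :func:`mutate` — applies a known random edit script (inserts, deletes,
  moves, attribute and text changes) to a document and returns both the
  result and the script, providing ground truth for round-trip oracles.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from lxml import etree

__all__ = [
    "EditScript",
    "make_fig2_pair",
    "make_role_change_pair",
    "make_glue_pair",
    "random_model",
    "mutate",
]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"


@dataclass
class EditScript:
    """Ordered list of primitive edits applied by :func:`mutate`."""

    seed: int
    edits: list = field(default_factory=list)

    def record(self, op: str, **details) -> None:
        self.edits.append({"op": op, **details})

    def __len__(self) -> int:
        return len(self.edits)


# -- worked example --------------------------------------------------------


def make_fig2_pair() -> tuple[str, str]:
    """The two versions of the minimal worked-example model.

    Version 1 holds species C, D, E and the reaction C+D⇄E; version 2 holds
    D, H, E and the reaction D+H⇄E, with the concentration of E changed.
    Only the reaction carries an id; the D subtrees are identical in both
    versions, so only they share a signature.
    """
    v1 = """<sbml>
  <listOfSpecies>
    <species name="C" initialConcentration="4"/>
    <species name="D"/>
    <species name="E" initialConcentration="2"/>
  </listOfSpecies>
  <listOfReactions>
    <reaction id="reaction1"/>
  </listOfReactions>
</sbml>
"""
    v2 = """<sbml>
  <listOfSpecies>
    <species name="D"/>
    <species name="H" initialConcentration="1"/>
    <species name="E" initialConcentration="3"/>
  </listOfSpecies>
  <listOfReactions>
    <reaction id="reaction1"/>
  </listOfReactions>
</sbml>
"""
    return v1, v2


def make_role_change_pair() -> tuple[str, str]:
    """Two versions where a species switches from modifier to reactant.

    In version 1 cdc2 modifies the dimer-formation reaction; in version 2 it
    is one of the reactants.  The overlay of the two reaction networks shows
    one deleted (modifier) edge, one inserted (reactant) edge and the
    reaction node marked as updated.
    """
    v1 = f"""<sbml xmlns="{SBML_NS}" level="2" version="4">
  <model id="cycle">
    <listOfSpecies>
      <species id="cyclin" name="cyclin"/>
      <species id="cdc2" name="cdc2"/>
      <species id="dimer" name="cyclin-cdc2 dimer"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="dimer_formation" name="cyclin-cdc2 dimer formation">
        <listOfReactants>
          <speciesReference species="cyclin"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="dimer"/>
        </listOfProducts>
        <listOfModifiers>
          <modifierSpeciesReference species="cdc2"/>
        </listOfModifiers>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
    v2 = f"""<sbml xmlns="{SBML_NS}" level="2" version="4">
  <model id="cycle">
    <listOfSpecies>
      <species id="cyclin" name="cyclin"/>
      <species id="cdc2" name="cdc2"/>
      <species id="dimer" name="cyclin-cdc2 dimer"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="dimer_formation" name="cyclin-cdc2 dimer formation">
        <listOfReactants>
          <speciesReference species="cyclin"/>
          <speciesReference species="cdc2"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="dimer"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
    return v1, v2


def make_glue_pair() -> tuple[str, str]:
    """Two versions where an identical listOfModifiers subtree hops between
    two different reactions, exercising the SBML glue rules.

    Reaction ``ra`` keeps its id in both versions but loses its modifier; a
    new reaction ``rb`` appears in version 2 carrying an identical modifier
    subtree.  Signature matching pairs the two listOfModifiers subtrees even
    though their reactions differ, which the glue rules must undo.
    """
    v1 = f"""<sbml xmlns="{SBML_NS}" level="2" version="4">
  <model id="glue">
    <listOfSpecies>
      <species id="sub" name="substrate"/>
      <species id="prod" name="product"/>
      <species id="mod" name="enzyme"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="ra" reversible="false">
        <listOfReactants>
          <speciesReference species="sub"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="prod"/>
        </listOfProducts>
        <listOfModifiers>
          <modifierSpeciesReference species="mod"/>
        </listOfModifiers>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
    v2 = f"""<sbml xmlns="{SBML_NS}" level="2" version="4">
  <model id="glue">
    <listOfSpecies>
      <species id="sub" name="substrate"/>
      <species id="prod" name="product"/>
      <species id="mod" name="enzyme"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="ra" reversible="false">
        <listOfReactants>
          <speciesReference species="sub"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="prod"/>
        </listOfProducts>
      </reaction>
      <reaction id="rb" reversible="true">
        <listOfReactants>
          <speciesReference species="prod"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="sub"/>
        </listOfProducts>
        <listOfModifiers>
          <modifierSpeciesReference species="mod"/>
        </listOfModifiers>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
    return v1, v2


# -- random models ---------------------------------------------------------

_WORDS = (
    "cyclin", "kinase", "dimer", "substrate", "complex", "enzyme",
    "promoter", "inhibitor", "ligand", "receptor", "phosphatase", "monomer",
)


def random_model(seed: int, n_species: int = 5, n_reactions: int = 3) -> str:
    """A deterministic toy SBML level 2 document.

    Species/reaction counts are exact; reactant/product/modifier wiring,
    names, concentrations and the optional kinetic-law math are drawn from
    the seeded generator, so the same seed always yields byte-identical
    output.
    """
    if n_species < 1:
        raise ValueError("n_species must be at least 1")
    if n_reactions < 0:
        raise ValueError("n_reactions must not be negative")
    rng = random.Random(seed)
    ns = SBML_NS
    root = etree.Element(f"{{{ns}}}sbml", nsmap={None: ns})
    root.set("level", "2")
    root.set("version", "4")
    model = etree.SubElement(root, f"{{{ns}}}model")
    model.set("id", f"model_{seed}")
    model.set("name", f"{rng.choice(_WORDS)} model")

    compartments = etree.SubElement(model, f"{{{ns}}}listOfCompartments")
    compartment = etree.SubElement(compartments, f"{{{ns}}}compartment")
    compartment.set("id", "cell")
    compartment.set("size", "1")

    species_list = etree.SubElement(model, f"{{{ns}}}listOfSpecies")
    species_ids = []
    for i in range(1, n_species + 1):
        sp = etree.SubElement(species_list, f"{{{ns}}}species")
        sid = f"s{i}"
        sp.set("id", sid)
        sp.set("name", f"{rng.choice(_WORDS)}_{i}")
        sp.set("compartment", "cell")
        sp.set("initialConcentration", str(round(rng.uniform(0.1, 10.0), 3)))
        species_ids.append(sid)

    if rng.random() < 0.5:
        parameters = etree.SubElement(model, f"{{{ns}}}listOfParameters")
        for i in range(1, rng.randint(1, 3) + 1):
            par = etree.SubElement(parameters, f"{{{ns}}}parameter")
            par.set("id", f"k{i}")
            par.set("value", str(round(rng.uniform(0.01, 5.0), 3)))

    if n_reactions:
        reactions = etree.SubElement(model, f"{{{ns}}}listOfReactions")
        for i in range(1, n_reactions + 1):
            rx = etree.SubElement(reactions, f"{{{ns}}}reaction")
            rx.set("id", f"r{i}")
            rx.set("reversible", rng.choice(("true", "false")))
            reactants = etree.SubElement(rx, f"{{{ns}}}listOfReactants")
            for sid in rng.sample(species_ids, k=min(rng.randint(1, 2), len(species_ids))):
                ref = etree.SubElement(reactants, f"{{{ns}}}speciesReference")
                ref.set("species", sid)
                if rng.random() < 0.3:
                    ref.set("stoichiometry", str(rng.randint(1, 3)))
            products = etree.SubElement(rx, f"{{{ns}}}listOfProducts")
            ref = etree.SubElement(products, f"{{{ns}}}speciesReference")
            ref.set("species", rng.choice(species_ids))
            if rng.random() < 0.4:
                modifiers = etree.SubElement(rx, f"{{{ns}}}listOfModifiers")
                ref = etree.SubElement(modifiers, f"{{{ns}}}modifierSpeciesReference")
                ref.set("species", rng.choice(species_ids))
            if rng.random() < 0.5:
                law = etree.SubElement(rx, f"{{{ns}}}kineticLaw")
                math = etree.SubElement(
                    law, "{http://www.w3.org/1998/Math/MathML}math"
                )
                ci = etree.SubElement(
                    math, "{http://www.w3.org/1998/Math/MathML}ci"
                )
                ci.text = f" k{rng.randint(1, 3)} "
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# -- mutation --------------------------------------------------------------

_MUTATION_KINDS = (
    "set_attribute",
    "add_attribute",
    "remove_attribute",
    "insert_node",
    "delete_node",
    "move_node",
    "set_text",
)


def _element_path(element: etree._Element) -> str:
    return element.getroottree().getpath(element)


def _elements(root: etree._Element) -> list:
    return [el for el in root.iter() if isinstance(el.tag, str)]


def mutate(doc: str, seed: int, n_edits: int) -> tuple[str, EditScript]:
    """Apply ``n_edits`` random primitive edits and return result + script.

    The script records each edit with the target's path at application time;
    applying the same seed to the same document is fully deterministic.
    """
    if n_edits < 0:
        raise ValueError("n_edits must not be negative")
    rng = random.Random(seed)
    parser = etree.XMLParser(resolve_entities=False, no_network=True, remove_comments=True)
    root = etree.fromstring(doc.encode("utf-8"), parser=parser)
    script = EditScript(seed=seed)

    for _ in range(n_edits):
        for _attempt in range(20):  # some edit kinds need a suitable target
            kind = rng.choice(_MUTATION_KINDS)
            if _try_edit(kind, root, rng, script):
                break
    return etree.tostring(root, pretty_print=True, encoding="unicode"), script


def _try_edit(kind: str, root, rng: random.Random, script: EditScript) -> bool:
    elements = _elements(root)
    if kind == "set_attribute":
        with_attrs = [el for el in elements if el.attrib]
        if not with_attrs:
            return False
        el = rng.choice(with_attrs)
        name = rng.choice(sorted(el.attrib))
        new = f"v{rng.randint(0, 9999)}"
        script.record("set_attribute", path=_element_path(el), name=name,
                      old=el.get(name), new=new)
        el.set(name, new)
        return True
    if kind == "add_attribute":
        el = rng.choice(elements)
        name = f"extra{rng.randint(0, 99)}"
        if name in el.attrib:
            return False
        value = f"v{rng.randint(0, 9999)}"
        script.record("add_attribute", path=_element_path(el), name=name, value=value)
        el.set(name, value)
        return True
    if kind == "remove_attribute":
        with_attrs = [el for el in elements if el.attrib]
        if not with_attrs:
            return False
        el = rng.choice(with_attrs)
        name = rng.choice(sorted(el.attrib))
        script.record("remove_attribute", path=_element_path(el), name=name,
                      old=el.get(name))
        del el.attrib[name]
        return True
    if kind == "insert_node":
        parent = rng.choice(elements)
        tag = rng.choice(("extraTag", "annotationLike", "note"))
        fresh = etree.Element(tag)
        fresh.set("id", f"new{rng.randint(0, 9999)}")
        if rng.random() < 0.3:
            fresh.text = rng.choice(_WORDS)
        position = rng.randint(0, len(parent))
        parent.insert(position, fresh)
        script.record("insert_node", parent=_element_path(parent), tag=tag,
                      position=position)
        return True
    if kind == "delete_node":
        candidates = [el for el in elements if el.getparent() is not None]
        if not candidates:
            return False
        el = rng.choice(candidates)
        script.record("delete_node", path=_element_path(el), tag=el.tag)
        el.getparent().remove(el)
        return True
    if kind == "move_node":
        candidates = [el for el in elements if el.getparent() is not None]
        if not candidates:
            return False
        el = rng.choice(candidates)
        subtree = set(el.iter())
        targets = [t for t in elements if t not in subtree]
        if not targets:
            return False
        target = rng.choice(targets)
        script.record("move_node", path=_element_path(el),
                      new_parent=_element_path(target))
        el.getparent().remove(el)
        target.insert(rng.randint(0, len(target)), el)
        return True
    if kind == "set_text":
        el = rng.choice(elements)
        if len(el) > 0 and el.text is None:
            return False  # avoid creating interleaved text content
        new = rng.choice(_WORDS) + str(rng.randint(0, 99))
        script.record("set_text", path=_element_path(el), old=el.text, new=new)
        el.text = new
        return True
    return False
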