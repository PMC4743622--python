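# modeldiff

Difference detection for versions of XML-encoded computational models of
biological systems (SBML and CellML).

Model repositories accumulate many coexisting versions of the same model —
curation fixes, extensions, format upgrades.  A line-based `diff` performs
poorly on XML: it is distracted by indentation, attribute order and element
shuffling, and it cannot say *which species or reaction* changed.
`modeldiff` compares two versions at the level of the document tree and of
the encoded reaction network, and communicates the differences as

* a **machine-readable XML delta** that is complete and invertible — given
  one version and the delta, the other version can always be reconstructed;
* a **human-readable report** (Markdown, ReStructuredText or HTML) listing
  the biologically relevant changes: species, parameters, reactions,
  compartments, events, math;
* a **difference-highlighted reaction network** (GraphML, DOT or JSON) in
  which deleted elements are red, inserted ones blue and updated ones
  yellow.

## The algorithm

Both documents are parsed into trees in which every node *n* carries a
weight

```
ω(n) = 1 + log(length(n))   if n is a text node
       1                    if n is a leaf element
       1 + Σ_{c ∈ children(n)} ω(c)   otherwise
```

and a signature σ(n), the SHA-256 digest of the node's canonical content
(tag, attributes in canonical order, child digests, normalised text), so
σ(n) = σ(m) exactly when the two subtrees are identical.  Indentation,
attribute order and comments never influence ω or σ.

A node correspondence between the trees is then built bottom-up and lazily
down in four phases: (1) nodes sharing a biological identifier (annotation
URI) or an `id` attribute are paired; (2) pairings are propagated upwards,
each mapped child suggesting its partner's parent with confidence ω;
(3) a max-weight priority queue finds identical subtrees by signature and
pairs them wholesale together with the bridging ancestors; (4) remaining
unmatched children of paired nodes are compared through an
attribute-distance matrix (share of differing attributes) and paired
greedily up to distance 0.9.  SBML/CellML glue rules then unpair atomic
constructs (`listOf*` containers, `speciesReference`, `variable`, …) whose
parents do not correspond, trading delta minimality for biological
significance.  The delta — disjoint sets of deletes, inserts, moves and
updates — follows directly from the final mapping.

## Worked example

The bundled toy fixture encodes the update of a reaction C+D⇄E to D+H⇄E in
which the concentration of E also changes:

```sh
modeldiff demo --out demo
modeldiff diff demo/toy-v1.xml demo/toy-v2.xml --report md --out out
cat out/report.md
```

prints

```markdown
# Model differences

- deleted species 'C'
- inserted species 'H'
- updated species 'E': attribute initialConcentration changed from '2' to '3'
```

i.e. the three real changes and nothing else — species D, which carries no
id at all, is recognised as unchanged through its subtree signature.  The
XML delta for the same pair (`--xml-delta`) contains exactly one node
delete, one node insert (each with its attributes) and one attribute
update:

```xml
<diff>
  <deletes>
    <node id="1" oldPath="/sbml[1]/listOfSpecies[1]/species[1]" oldParent="/sbml[1]/listOfSpecies[1]" oldChildNo="1" oldTag="species"/>
    ...
  </deletes>
  <inserts>
    <node id="4" newPath="/sbml[1]/listOfSpecies[1]/species[2]" newParent="/sbml[1]/listOfSpecies[1]" newChildNo="2" newTag="species"/>
    ...
  </inserts>
  <moves/>
  <updates>
    <attribute id="7" oldPath="/sbml[1]/listOfSpecies[1]/species[3]" newPath="/sbml[1]/listOfSpecies[1]/species[3]"
               name="initialConcentration" oldValue="2" newValue="3"/>
  </updates>
</diff>
```

Because the delta is complete it can be applied in both directions:

```sh
modeldiff patch demo/toy-v1.xml out/delta.xml            # -> version 2
modeldiff patch demo/toy-v2.xml out/delta.xml --invert   # -> version 1
```

The same works from Python:

```python
from modeldiff import diff, patch, invert_delta
result = diff(xml_v1, xml_v2)
assert patch(result.t1, result.delta).canonically_equal(result.t2)
assert patch(result.t2, invert_delta(result.delta)).canonically_equal(result.t1)
```

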