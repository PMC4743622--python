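# Methods

This note documents the model of document differencing implemented by
`modeldiff`, the tunable parameters, the numerical and design choices made
where the procedure is genuinely open, and the limits of what the bundled
synthetic fixtures can show.

## Canonical document model

A version of a model is a well-formed XML document.  It is translated into
a tree of element and text nodes in which

* whitespace-only text is dropped and remaining text is stripped of
  surrounding whitespace (indentation never constitutes a model change);
* comments and processing instructions are discarded;
* element names are compared by expanded name (namespace URI + local
  name); namespace *declarations* (`xmlns*`) are bookkeeping, not content,
  and are excluded from attribute sets;
* attribute order is canonicalised (sorted by name) wherever attributes
  enter a digest or a distance.

Two documents are *canonically equal* when their root signatures agree;
this is the equality used by every round-trip check.

**Weights.** ω(text) = 1 + ln(length); ω(leaf element) = 1;
ω(inner element) = 1 + Σ ω(children).  The logarithm base is not
semantically constrained — weights only feed orderings and confidence sums
— so the natural logarithm is used throughout.  Parent weights strictly
exceed child weights, and ω ≥ 1 everywhere.

**Signatures.** σ(n) is the SHA-256 digest of the node's tag, its
attributes as sorted `name=value` pairs, its children's digests in
document order, and (for text nodes) the normalised text, with NUL
(`\x00`) separators — NUL cannot occur in XML content, so the layout is
unambiguous, and element and text payloads carry distinct prefixes.
SHA-256 was chosen as the ubiquitous SHA-2 variant; at 256 bits, digest
collisions are not a practical concern, and the test suite additionally
checks on a thousand small random trees that equal signatures imply
canonical subtree equality.

**Addressing.** Every node is addressed by an absolute XPath with 1-based
positional predicates over local names (`/sbml[1]/model[1]/species[2]`,
text nodes as `text()[k]`).  Positions count retained children only.  The
produced paths are valid XPath and are verified against lxml's XPath
engine as an independent oracle.  Documents with same-local-name siblings
in *different* namespaces would be ambiguous under this addressing; such
documents do not occur in SBML/CellML practice.

## Matching

The mapping engine pairs nodes of the old tree T1 with nodes of the new
tree T2; the mapping is injective in both directions, and the two roots
are always paired (the only pair whose tags may differ — a root rename is
reported as the single node-level update).  Four phases run in fixed
order; each is idempotent on a stable mapping.

1. **By identifier.**  Biological identifiers — attribute values inside
   `annotation` subtrees matching identifier-URI patterns
   (`identifiers.org/…`, `urn:miriam:…`) — take priority over plain `id`
   attributes, because they survive renumbering of ids.  A URI is only
   used when it occurs exactly once per document; duplicate `id` values
   are likewise excluded (an identifier must identify).  Pairs require
   equal tags and never overwrite existing pairs.

2. **Bottom-up propagation.**  In a post-order traversal of T2, each
   mapped child suggests its partner's parent with confidence equal to
   the child's weight, so large agreeing subtrees dominate.  An
   unconnected node adopts the unconnected same-tag candidate with the
   highest summed confidence; ties break by T1 document order, making the
   output deterministic.

3. **Top-down (signature) propagation.**  A priority queue over T2,
   largest subtree first (ties by document order), looks for unmapped T1
   nodes with an identical signature.  A candidate qualifies when one of
   its ancestors is already paired with an ancestor of the queued node
   within the *chase depth*; among qualifying candidates the one whose
   qualifying ancestor is nearest wins (ties by document order).  The two
   identical subtrees are then paired node by node, as are the unpaired
   same-tag ancestors bridging up to the discovered pairing.  Nodes whose
   signature finds no candidate have their children enqueued, so the
   total queued weight strictly decreases and the phase terminates.

   The chase depth is `1 + ceil((ω(n)/ω(root(T2))) · height(T2))`
   (configurable via the `chase_depth` argument): leaves may climb two
   levels — parent and grandparent — while document-scale subtrees may
   climb to the root.  The additive floor of one extra level is needed
   for a leaf to anchor through an unmapped parent to a mapped
   grandparent, the situation of the worked example's D node, whose
   anchoring in turn adds the pairing of the two species containers.

4. **Optimization.**  For every mapped pair, visited top-down in T2
   document order (so children of pairs added earlier in the sweep are
   themselves processed), a distance matrix over the still-unmatched
   children is built: ∞ for differing tags, otherwise the share of
   differing attributes over the union of attribute names, 0 when neither
   node has attributes.  Matrix entries are taken greedily in ascending
   distance (row-major tie-break) while ≤ 0.9 — the inclusive threshold
   guarantees that nodes with nothing in common are never paired, while a
   single changed attribute among several keeps a pair together.

**Domain glue rules.**  In SBML, `listOf*` containers and the
reaction-/event-bound tags `speciesReference`,
`modifierSpeciesReference`, `trigger`, `eventAssignment`, `delay` and
`priority` are atomic parts of their parents; in CellML, `variable` and
`reaction` belong to their enclosing `component`.  A pair of such nodes
whose parents (components) are not paired with each other is dropped,
together with the pairs of all its descendants — a detached subtree must
not remain partially mapped, or the delta would contain moves across
unrelated entities.  Rules iterate to a fixpoint, only ever remove pairs,
and are idempotent.  They deliberately enlarge the delta (a cross-reaction
"move" of a modifier list becomes an explicit delete + insert) in exchange
for biologically meaningful output; `--no-domain-rules` disables them.

## Delta semantics

From the final mapping: unmapped T1 nodes and their attributes are
deletes; unmapped T2 nodes and their attributes are inserts; a mapped node
whose parents are not paired together, or whose position among its mapped
siblings changed, is a move (with old/new parent paths and 1-based child
numbers); attribute differences on mapped pairs become
deletes/inserts/updates; differing text of a mapped text pair is a text
update.  Sibling reordering is detected per parent pair with a longest
increasing subsequence over the partners' child indices — mapped children
outside the LIS move, which minimises the move count and is deterministic.
Moves carry document nodes only; the rare relocated text pair is encoded
as a text delete plus insert instead.

The XML encoding uses root element `diff` with the four sections
`deletes`, `inserts`, `moves`, `updates` holding `node`, `attribute` and
`text` elements; attributes appear in the fixed order `id`, `oldPath`,
`newPath`, `oldParent`, `newParent`, `oldChildNo`, `newChildNo`,
`oldTag`, `newTag`, `name`, `oldValue`, `newValue`, and operation ids are
sequential integers, so serialisation is byte-stable and round-trips
field-for-field.  Node tags are stored in Clark notation (`{uri}local`)
so a patch can recreate namespaced elements exactly.

**Patching.**  All operations addressed in pre-patch coordinates
(deletes, move sources, attribute/text updates) are resolved to node
objects *before* any structural change, so path validity is independent of
application order.  Then: value-level changes are applied; deleted
subtrees are detached deepest-first; move sources are detached; moves and
node/text inserts are attached in ascending (destination depth,
destination child number) — a single ordered structural phase rather than
strictly "moves before inserts", because a moved node's destination parent
may itself be an inserted node; finally attribute inserts are applied in
post-patch coordinates.  Since surviving siblings keep their relative
order and every addition lands at its exact final index in ascending
order, the resulting child sequences equal the target's.  A failing
operation raises an error naming the operation id and no partial result
is ever returned (patching works on a copy).  Completeness and
invertibility — `patch(T1, δ) ≡ T2` and `patch(T2, δ⁻¹) ≡ T1` — are
exercised over 200 seeded (model, mutant) pairs plus property tests on
generic random documents.

## Reports and difference graphs

The report keeps only changes owned by a model-relevant entity (SBML:
species, parameters, reactions, compartments, rules, events, function and
unit definitions; CellML: components, variables, reactions, connections,
units); container-only operations surviving as formatting artefacts are
omitted.  Entities display their `name`, else `id`, else path; changes
inside `math` subtrees are summarised as "math changed" on the owning
entity.  Markdown, ReST and HTML renderings share the same change lines.

The reaction network is extracted as a bipartite graph (species and
reaction nodes; directed reactant/product/modifier edges, SBML via
`speciesReference`/`modifierSpeciesReference`, CellML via
`variable_ref`/`role`).  The two versions' networks are merged through the
node mapping: merged nodes have origin `both` and are `updated` when
their document attributes or incident edge sets changed; version-local
nodes/edges are `deleted`/`inserted`.  Exports: GraphML (hand-built,
verified through networkx's reader as an independent parser), DOT and a
flat JSON schema, all carrying origin/status/role plus a configurable
colour map (default: deletes red, inserts blue, updates yellow; optional
stoichiometry edge labels when present).  Documents without reaction
markup raise a not-supported error rather than guessing a network.

## Synthetic fixtures

The fixture module generates everything the tests need at run time.  The
worked-example pair is deliberately minimal: three species and one
reaction per version; only the reaction carries an `id`, species carry
`name`/`initialConcentration` (the E nodes must differ *only* in their
concentration attribute, so none of the species may carry an id, or the
by-identifier phase would pair them prematurely).  `random_model`
produces small but validator-clean SBML Level 2 documents (defaults: 5
species, 3 reactions — large enough for non-trivial wiring, small enough
that a 200-pair suite runs in about a second); `mutate` applies a known
seeded edit script (attribute set/add/remove, node insert/delete/move,
text change) and returns it as ground truth.

What the fixtures do **not** emulate: real repository histories (bursts
of correlated edits, format-version migrations), deep MathML, RDF
annotation stacks, or documents of repository scale.  Passing the
round-trip suite therefore demonstrates the correctness of the
delta/patch machinery and of the matching heuristics on toy models, not
mapping *quality* on real histories — the matcher is an explicit
heuristic and no minimality of the edit script is claimed.

## Known limitations

* MathML is diffed as generic subtrees; no semantic equivalence of
  expressions is attempted.
* Mapping-by-identifier uses exact identifier equality; ontological
  similarity between different identifiers is not considered.
* No SBGN output and no rendered images — graph rendering is delegated to
  downstream viewers.
* Deltas relate exactly two versions; composition across longer histories
  and three-way merge are out of scope.
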