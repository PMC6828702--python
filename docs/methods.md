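# Methods

This note records the modelling choices behind `empusa`, the points where
the design was genuinely open, and what the test harness does and does not
demonstrate.

## Schema model

A schema is a single-parent tree of classes, each owning an ordered list of
typed, multiplicity-constrained properties, plus value sets (controlled
vocabularies) kept in a separate IRI space under an `EnumeratedValue` root.
Invariants are enforced eagerly at construction: UpperCamelCase class names
and lowerCamelCase property names, acyclic single inheritance, resolvable
class/value-set targets, and no property redefinition along an inheritance
chain. Redefinition is forbidden rather than resolved by override because
overriding would make the flattened property list — the unit every emitter
and the validator works from — ambiguous.

Multiplicities are restricted to the four forms `0..1`, `1..1`, `0..N`,
`1..N`; the unbounded maximum is an explicit singleton (`UNBOUNDED`), never
a sentinel integer. The `=` (ordered) and `~` (numbered) markers are legal
only on unbounded forms, since ordering a single value is meaningless.

**Counting rule.** `schema_stats` counts classes, *owned* (non-inherited)
properties, and value sets; value-set member classes are tallied with their
set, not with the classes. Two identically named properties on sibling
classes count twice (they are distinct definitions). This rule is what the
bundled locations fixture's 16/17/1 row is measured under.

## The definition dialect

The property dialect is line-oriented: `[# comment]\n<name> <target>
<multiplicity>`, one property per line, comments attaching to the next
property as its description. Target tokens: `xsd:<datatype>` (five
primitives), a (possibly prefixed) class name, `@Name` for value sets,
`<iri>` or bare `IRI` for external references. The generic `IRI` target is
represented internally as an external reference to `rdfs:Resource`. Property
IRIs are minted as `<base><name>`, so the same name on sibling classes
shares one predicate IRI — deliberate, matching how instance data uses one
predicate per concept. Parsing is whitespace- and line-ending-insensitive;
every syntax error carries the owning class IRI and 1-based line number.
Per-property facets (regex, ranges) are not supported.

The definition file itself is an RDF graph: classes as `owl:Class`,
hierarchy as `rdfs:subClassOf`, the dialect block as a plain-literal
annotation (`propertyDefinitions`), names as `rdfs:label`, documentation as
`skos:definition` / `skos:scopeNote` / `skos:editorialNote`, feature-table
labels under a `ddbjLabel` annotation property and cross-ontology links as
`skos:exactMatch`. Because annotation values are plain literals the file
stays editable in generic OWL editors. A class without an explicit
definition falls back to its label/name, so minimal hand-written graphs
remain loadable while emitted files always carry full annotations.

## Emitters

All emitters are deterministic template writers (classes, members,
restrictions sorted by IRI; property lines in defined order), so an
unchanged schema regenerates byte-identically — a property any downstream
version control relies on.

**OWL.** Each property becomes an anonymous
`owl:Restriction`/`owl:allValuesFrom` subclass axiom; `owl:minCardinality 1`
is emitted iff the property is required and `owl:maxCardinality 1` iff at
most one value is allowed. `owl:someValuesFrom` is never emitted: it cannot
enforce that *all* referenced objects have the expected type. Property
declarations are `owl:DatatypeProperty` or `owl:ObjectProperty` by use, and
degrade to `rdf:Property` if a predicate IRI is used both ways.

**ShEx.** One shape per class, labelled by the class IRI, carrying the
class's *flattened* properties so every shape is self-contained and
engine-portable (no shape-inclusion feature needed). Shapes are `CLOSED`
with `EXTRA rdf:type` — closed because only closed shapes surface predicate
typos, `EXTRA rdf:type` so instances may carry their type triples.
Cardinality maps `0..1→?`, `1..1→`(nothing)`, 0..N→*, 1..N→+`. Value-set
targets become value constraints enumerating all (transitive) members.
Class targets become `@<target> OR @<descendant> ...`, which is what makes
subclass substitutability hold under closed shapes. Ordered-list properties
reference auxiliary RDF-collection shapes (`[rdf:nil] OR CLOSED {rdf:first
…; rdf:rest @<self>}`, plus a non-empty variant when at least one element is
required); numbered-list properties anchor the container node with a `.`
wildcard, since ShExC has no way to express the open-ended `rdf:_n`
predicate family — container numbering is checked by the validator instead,
and the artifact header says so.

## Closed-world validator

Every subject typed with a schema class is checked against the class's
flattened properties: absence of a required link, excess cardinality,
predicates outside the property list (other than `rdf:type`), object type
compatibility (target class or any descendant; untyped objects are their
own violation kind), value-set membership, and well-formedness of
collections (single `rdf:first`/`rdf:rest` per cell, nil-terminated,
acyclic) and containers (single value per slot, contiguous numbering from
`rdf:_1`). Violations are deduplicated by (kind, subject, predicate) and
reported as data, never exceptions; only an unreadable input graph raises.

Decisions where the design was open:

- **Multiple `rdf:type` values** are validated independently per schema
  type (per-shape closed-world semantics).
- **Foreign types.** A type IRI inside the schema namespace that is not a
  class is a `non_schema_type` violation; types from other namespaces are
  ignored — they belong to ontologies this validator cannot closed-world
  check.
- **External-IRI targets** are checked syntactically (absolute IRI) only
  and never dereferenced.
- **Literals.** Plain literals satisfy string targets; numeric/boolean/URI
  targets require the matching XSD datatype, but an *untyped* literal with
  a valid lexical form is accepted with a warning rather than a violation
  (common in hand-converted data); a wrongly *typed* literal is always a
  violation.
- **Blank nodes** are allowed as subjects and objects everywhere except as
  value-set members.
- **Non-unique IRIs** are prevented at the production side (the binding
  store refuses IRI reuse) rather than detected by the validator, where a
  textual duplicate is invisible after graph parsing.

## Data bindings

Generated Python code mirrors schema inheritance in class inheritance; all
checking logic lives in a shared runtime so generated modules stay thin.
Accessor kinds follow multiplicity alone: `set_`/`get_` for single-valued,
`add_`/`remove_`/`get_` for unbounded properties. Value sets become `Enum`s
over member IRIs. Membership and types are checked at set-time (fast
failure) *and* at export (backstop). Export refuses to serialize while any
instance misses a required property — reporting the complete list, not the
first hit — or references an object outside the store. Instance IRIs are
caller-supplied or minted as `<base>instance/<Class>/<n>`, collision-checked
against the store. Ordered lists serialize as Turtle collections, numbered
lists as `rdf:_n` containers; subjects serialize in insertion order through
a deterministic writer, so identical build sequences give identical files.
Reserved-word collisions in generated identifiers are escaped with a
trailing underscore and logged.

## Documentation generator

One page per class and value set at `<out>/<Name>/index.md`, mirroring the
IRI namespace so a static server rooted at the base IRI makes class IRIs
resolvable. Inherited properties are listed in a separate section grouped
by ancestor; per-property anchors are `#<propertyName>`. A mkdocs-style
`mkdocs.yml` enumerates all pages; the generator emits configuration and
Markdown only and never invokes a site builder.

## The genomic-locations fixture

The location model is deliberately restructured relative to its
sequence-ontology ancestry: strand is an optional value-set property of
`Region`, `BaseLocation` and `InBetweenLocation` (not a `Position`
subclass); the reference sequence is a property of `Location`, so a
collection's member regions can each point at different sequences;
`BaseLocation` and `InBetweenLocation` are direct children of `Location`;
fuzzy positions (`Before`, `After`, `InRange`, `OneOf`) carry plain
integers, preventing arbitrarily nested position objects; there are no
N-/C-terminal position classes (protein coordinates count from the
N-terminus; C-side positions are derivable from sequence length) and no
reflective begin-of/end-of properties.

The published overview row for this domain (16 classes, 17 properties, 1
value set) names twelve classes outright. Under the counting rule above the
strand vocabulary cannot contribute to the class tally, so the remaining
four are reconstructed: the ordered and unordered variants of
`CollectionOfRegions` (the collection semantics are explicitly "ordered or
unordered") and `Gap`/`KnownLengthGap` (assembly gaps, the `gap()`/`gap(N)`
operators of flat-file location strings). `BaseLocation.at` and
`InBetweenLocation.after` are the reconstructed names for the two
position-object links; the full enumeration ships in
`locations_manifest.json` for audit.

Coordinates are 1-based, fully closed (the flat-file convention; the toy
GFF3 input uses the same convention and maps identically). An in-between
location `a^b` is stored as the position of the preceding base `a`, with
`b = a + 1` enforced for same-sequence strings. Encoding `complement(...)`
selects the reverse strand; plain spans default to the forward strand only
on double-stranded DNA, and no strand is recorded otherwise. Sequence
strandedness is a demo-schema value set {DoubleStrandedDNA,
SingleStrandedDNA, RNA, Protein}; only the first admits stranded locations
(RNA treated as single-stranded), enforced by `strand_rule_check` as a
store-level semantic rule with its own violation kind (`strand_rule`),
distinct from the eight structural kinds. Tool-specific provenance classes
(e.g. a `Blast` record with a bit score) are deliberately *not* part of the
schema; `extend_with_provenance_subclass` grafts them under
`ProvenanceAnnotation` into a copy, so the same instance either validates
(extended schema) or is flagged as a non-schema type (original).

## Conformance testkit

Random schemas draw properties over all five primitives, class references
(any class, so reference cycles occur), value sets and external IRIs, all
four multiplicities and both list markers; all randomness flows through one
seeded generator, and equal seeds give byte-identical schemas. The instance
generator allocates typed nodes first and links second, so required
reference cycles are satisfiable by construction; literals are short ASCII
strings and integers below 10⁶ to keep graphs human-inspectable. Mutations
make the minimal edit inducing exactly one violation kind — e.g. the extra
value added for a cardinality fault is itself type-correct, the predicate
typo is applied to an occurrence whose removal is harmless, and the
untyped-node fault never untypes a self-reference (which would silence the
only witness). A kind with no site in a given graph (say, a malformed list
in a schema without list properties) raises `NotApplicable` and is excluded
rather than counted as detected.

What the synthetic data does *not* emulate: literal edge cases (language
tags, exotic datatypes, huge strings), blank-node subjects, multi-typed
instances, cross-document IRI collisions, and graphs at triple-store scale.
Passing the suite therefore demonstrates the closed-world contract over the
schema constructs, not robustness to arbitrary real-world RDF.

## Independent ShEx engine

`empusa.shexc` is a self-contained parser/evaluator for exactly the ShExC
subset the emitter produces (prefixes, `CLOSED`/`EXTRA`, `? * +`
cardinalities, datatypes, value sets, `IRI`, `.`, shape references, `OR`).
It never sees the schema object — only ShExC text and an `rdflib` graph —
so it provides a genuinely independent conformance verdict. Recursive shape
references are evaluated coinductively (assumed satisfied while under test,
the greatest-fixpoint reading) with memoized per-(graph, node, shape)
verdicts; without memoization, cyclic reference structures make the search
exponential. The driver maps each typed node to the shape labelled by its
type and treats an in-namespace type without a shape as nonconformant.
Verdict divergence from the built-in validator is permitted only where the
validator deliberately checks more than the emitted shapes express:
untyped-node attribution and list/container well-formedness. The
agreement suite asserts that every observed divergence falls in these two
categories.

## Problem sizes and numerical choices

The default test suite and the acceptance script use: 20 schemas × 8 kinds
× 50 seeds for the mutation suite (≈7,000–8,000 applicable mutations, since
not every kind is inducible on every graph), 200+ graphs for engine
agreement, 100 schemas for the emit/parse round trip, 18 canonical location
strings, and 100 binding-built stores (10 schemas × 10 stores) for the
export closure; random schemas use 6–20 classes and instance graphs 5–8
seed instances. These sizes keep any single check in seconds while covering
every construct; all are trivially scalable through the testkit parameters.
There is no floating-point tolerance anywhere: every comparison in the
toolchain (stats, round trips, verdicts) is exact, and doubles are
serialized via `repr` so they re-parse to the same value.

## Known limitations

- No OWL reasoning: subsumption is the explicit `rdfs:subClassOf` tree;
  imports are not resolved and nothing is inferred.
- The ShEx engine implements only the emitted subset; it is an oracle for
  this toolchain, not a general ShEx processor.
- The GenBank codec covers the location grammar used by the fixture
  (spans, fuzziness, ranges, one-of, in-between, join/order/complement,
  gaps); remote-accession references (`J00194.1:1..100`) and
  `complement` nesting other than around spans and whole joins are not
  canonicalized.
- Bindings are generated for one host language; the template-driven
  generator keeps per-language code isolated so further targets can be
  added without touching the model.
- The numbered-list container is anchored but not element-typed in ShEx
  (`rdf:_n` is an open predicate family); element checks live in the
  validator only.
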