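# empusa

An ontology-to-toolchain compiler for semantic genome annotation.

RDF makes heterogeneous life-science data integrable, but an RDF graph has no
enforced structure: the ontology *describes* the intended shape of the data
without constraining it, because OWL reasons under the open-world assumption
(a missing obligatory link is merely "unknown", never an error). In practice,
converting annotation pipelines' output to RDF produces predicate typos,
instances with missing attributes, untyped nodes and non-unique IRIs that no
OWL processor will ever flag. `empusa` closes that gap with a *gate-keeping*
toolchain: one schema definition drives generation of every artifact that
touches the data, so the ontology, the data producers and the validator can
never drift apart.

From a single definition file — OWL classes plus per-class property blocks in
a simplified ShEx dialect — the compiler produces:

1. an **OWL ontology** (every property as an `owl:allValuesFrom` restriction
   with optional min/max cardinality 1; `owl:someValuesFrom` is never used);
2. a **full ShEx schema** of closed shapes for conformance testing of
   instance data under the closed-world interpretation;
3. a **typed Python data-binding API** whose setters type-check their
   arguments and whose Turtle export refuses to serialize incomplete data —
   data built through it is correct by construction;
4. browsable **Markdown documentation** (mkdocs layout mirroring the IRI
   namespace, so class IRIs resolve to their own pages).

An independent closed-world **validator** checks any RDF graph against the
schema and reports eight structural violation kinds (unknown predicate,
missing required property, cardinality exceeded, wrong target type, untyped
node, value-set violation, malformed list, non-schema type).

## The schema language

Classes are ordinary `owl:Class` nodes (editable in Protégé); properties live
in a plain-literal annotation `propertyDefinitions`, one per line:

```
# the amino acid sequence
sequence xsd:string 1..1
regulatoryClass @RegulatoryClass 1..1
memberRegions Region =1..N
xref IRI 0..N
```

A property's target is a primitive (`xsd:string`, `xsd:integer`,
`xsd:double`, `xsd:boolean`, `xsd:anyURI`), another class, a value set
(`@Name` — a controlled vocabulary defined as a subtree under the
`EnumeratedValue` class), or an external IRI. The multiplicity is one of
`0..1`, `1..1`, `0..N`, `1..N`; on the unbounded forms a leading `=` stores
the values as an ordered RDF collection and `~` as a numbered
`rdf:_1, rdf:_2, ...` container.

## Bundled fixture: genomic locations

The package ships a worked sub-ontology for genomic locations (16 classes,
17 properties, 1 value set), FALDO-inspired but deliberately restructured:
strand is a property of `Region`/`BaseLocation`/`InBetweenLocation` rather
than a `Position` subclass, the reference sequence sits on the `Location` (so
collections of regions may span sequences), fuzzy positions hold plain
integers, and there are no N-/C-terminal position classes (protein indexes
count from the N-terminal side). A reduced feature/document/provenance demo
schema, a GenBank location-string codec (`join`, `order`, `complement`,
`<`/`>` fuzziness, `a^b` in-between, `a.b` ranges, `one-of`, `gap`) and a
3-gene toy annotation exercise the whole toolchain end to end.

## Worked example

```python
from empusa.gbol import (GBOL, build_demo_schema, build_locations_schema,
                         encode_location, decode_location, get_api,
                         new_annotation_store)
from empusa.validate import validate_graph
from rdflib import Graph, URIRef
from rdflib.namespace import RDF

print("stats:", tuple(build_locations_schema().stats()))

api = get_api()                      # generated bindings for the demo schema
store = new_annotation_store()
chrom = api.Sequence(store, iri=GBOL + "i/chr1")
chrom.set_sequence("ACGTACGTACGT")
chrom.set_strandType(api.Strandedness.DoubleStrandedDNA)
iri = encode_location("complement(join(3..5,7..9))", GBOL + "i/chr1", store)
print("encoded as:", store.get(iri).CLASS_IRI.rsplit("/", 1)[-1])
print("round trip:", decode_location(store, iri))

demo = build_demo_schema()
g = Graph()                          # a protein lacking its 1..1 sequence
protein = URIRef(GBOL + "i/protX")
g.add((protein, RDF.type, URIRef(GBOL + "Sequence")))
g.add((protein, URIRef(GBOL + "strandType"), URIRef(GBOL + "Protein")))
print(validate_graph(g, demo).to_text())
```

prints

```
stats: (16, 17, 1)
encoded as: OrderedCollectionOfRegions
round trip: complement(join(3..5,7..9))
does NOT conform: 1 violation(s) over 1 checked instance(s)
  missing_required       http://gbol.life/0.1/i/protX [http://gbol.life/0.1/sequence]  required property absent
```

The stats triple is the locations sub-ontology's class/property/value-set
count; the two-exon reverse-strand location round-trips through the typed
instance model byte-identically; and the closed-world validator reports the
protein's missing amino-acid sequence instead of assuming (as OWL would)
that it exists somewhere unstated.

## Command line

```
empusa fixture  --out fixtures/                 # materialize bundled fixture
empusa stats    --input fixtures/gbol_locations.ttl
empusa generate --input schema.ttl [--owl F] [--shex F] [--api D] [--docs D]
empusa validate --schema schema.ttl --data data.ttl [--report out.json]
```

`validate` exits 0 iff the data conforms (1 on violations, 2 on usage
errors), so it slots directly into pipelines.

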