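"""Emit the OWL ontology and the full ShEx schema for a :class:`Schema`.

Both artifacts are produced by deterministic template writers (classes
and properties ordered by IRI), so an unchanged schema always yields
byte-identical files.  The OWL mapping follows the "all values from"
discipline: every property becomes an ``owl:allValuesFrom`` restriction
(never ``owl:someValuesFrom``), with ``owl:minCardinality 1`` iff the
multiplicity requires the property and ``owl:maxCardinality 1`` iff at
most one value is allowed.

The ShEx schema is closed-world: one ``CLOSED`` shape per class (with
``EXTRA rdf:type`` so instances may carry their type triples), carrying
the class's *flattened* property list so each shape is self-contained.
Ordered-list properties (``=``) are expressed through auxiliary
RDF-collection shapes; numbered-list properties (``~``) use
``rdf:_1, rdf:_2, ...`` container membership, whose numbering ShExC
cannot constrain — the shape only anchors the container node and the
built-in validator checks the numbering itself.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    ClassDef,
    OrderedKind,
    PropertyDef,
    Schema,
    TargetKind,
)
from .reader import DDBJ_LABEL, ENUMERATED_VALUE

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"


@dataclass(frozen=True)
class GeneratedArtifact:
    """One emitted file: its kind, relative path and full text content."""

    kind: str   # "owl" | "shex" | "doc" | "config" | "source" | "data"
    path: str
    content: str

    def write(self, out_dir) -> None:
        from pathlib import Path
        target = Path(out_dir) / self.path
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_text(self.content, encoding="utf-8")


# ---------------------------------------------------------------------------
# OWL


def _owl_target_iri(prop: PropertyDef) -> str:
    if prop.target.kind is TargetKind.PRIMITIVE:
        return prop.target.datatype_iri
    return prop.target.target_iri


def _annotation_triples(schema: Schema, iri: str, ann) -> list:
    lines = [f'    skos:definition "{_esc(ann.definition)}" ;']
    if ann.usage_comment:
        lines.append(f'    skos:scopeNote "{_esc(ann.usage_comment)}" ;')
    if ann.editorial_comment:
        lines.append(f'    skos:editorialNote "{_esc(ann.editorial_comment)}" ;')
    if ann.ddbj_label:
        lines.append(f'    <{schema.base_iri}{DDBJ_LABEL}> "{_esc(ann.ddbj_label)}" ;')
    for match in sorted(ann.exact_matches):
        lines.append(f"    skos:exactMatch <{match}> ;")
    return lines


def _esc(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def emit_owl(schema: Schema) -> GeneratedArtifact:
    """Emit the OWL ontology (Turtle) for ``schema``."""
    base = schema.base_iri
    out: list = []
    out.append("@prefix owl: <http://www.w3.org/2002/07/owl#> .")
    out.append(f"@prefix rdf: <{RDF_NS}> .")
    out.append("@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .")
    out.append("@prefix skos: <http://www.w3.org/2004/02/skos/core#> .")
    out.append(f"@prefix xsd: <{XSD_NS}> .")
    out.append("")
    out.append(f"<{base}> a owl:Ontology .")
    out.append(f'<{base}{DDBJ_LABEL}> a owl:AnnotationProperty .')
    out.append("")

    # Property declarations, one per distinct IRI.  A property used with a
    # literal target anywhere is a DatatypeProperty, otherwise an
    # ObjectProperty; mixed use degrades to rdf:Property.
    kinds: dict = {}
    descriptions: dict = {}
    for cls in schema.classes.values():
        for prop in cls.properties:
            is_data = prop.target.kind is TargetKind.PRIMITIVE
            kinds.setdefault(prop.iri, set()).add(is_data)
            if prop.description and prop.iri not in descriptions:
                descriptions[prop.iri] = prop.description
    for iri in sorted(kinds):
        used = kinds[iri]
        decl = ("owl:DatatypeProperty" if used == {True}
                else "owl:ObjectProperty" if used == {False} else "rdf:Property")
        line = f"<{iri}> a {decl}"
        if iri in descriptions:
            line += f' ;\n    rdfs:comment "{_esc(descriptions[iri])}"'
        out.append(line + " .")
    if kinds:
        out.append("")

    for iri in sorted(schema.classes):
        cls = schema.classes[iri]
        out.append(f"<{iri}> a owl:Class ;")
        if cls.parent is not None:
            out.append(f"    rdfs:subClassOf <{cls.parent}> ;")
        out.append(f'    rdfs:label "{_esc(cls.name)}" ;')
        out.extend(_annotation_triples(schema, iri, cls.annotations))
        out[-1] = out[-1].removesuffix(" ;") + " ."
        for prop in sorted(cls.properties, key=lambda p: p.iri):
            target = _owl_target_iri(prop)
            out.append(f"<{iri}> rdfs:subClassOf [ a owl:Restriction ; "
                       f"owl:onProperty <{prop.iri}> ; "
                       f"owl:allValuesFrom <{target}> ] .")
            if prop.multiplicity.min == 1:
                out.append(f"<{iri}> rdfs:subClassOf [ a owl:Restriction ; "
                           f"owl:onProperty <{prop.iri}> ; "
                           f'owl:minCardinality "1"^^xsd:nonNegativeInteger ] .')
            if not prop.multiplicity.unbounded:
                out.append(f"<{iri}> rdfs:subClassOf [ a owl:Restriction ; "
                           f"owl:onProperty <{prop.iri}> ; "
                           f'owl:maxCardinality "1"^^xsd:nonNegativeInteger ] .')
        out.append("")

    if schema.value_sets:
        ev = f"{base}{ENUMERATED_VALUE}"
        out.append(f"<{ev}> a owl:Class ;")
        out.append('    skos:definition "Root class under which all value sets are defined." .')
        for vs_iri in sorted(schema.value_sets):
            vs = schema.value_sets[vs_iri]
            out.append(f"<{vs_iri}> a owl:Class ;")
            out.append(f"    rdfs:subClassOf <{ev}> ;")
            out.append(f'    rdfs:label "{_esc(vs.name)}" ;')
            if vs.annotations is not None:
                out.extend(_annotation_triples(schema, vs_iri, vs.annotations))
            out[-1] = out[-1].removesuffix(" ;") + " ."
            for member in sorted(vs.members):
                par = vs.members[member] or vs_iri
                out.append(f"<{member}> a owl:Class ; rdfs:subClassOf <{par}> .")
        out.append("")

    return GeneratedArtifact(kind="owl", path="ontology.ttl",
                             content="\n".join(out).rstrip() + "\n")


# ---------------------------------------------------------------------------
# ShEx


_CARDINALITY = {(0, False): " ?", (1, False): "", (0, True): " *", (1, True): " +"}


def _value_expr(schema: Schema, prop: PropertyDef) -> str:
    """ShExC value expression for a (non-list) occurrence of the target."""
    t = prop.target
    if t.kind is TargetKind.PRIMITIVE:
        return f"xsd:{t.datatype}"
    if t.kind is TargetKind.EXTERNAL_IRI:
        return "IRI"
    if t.kind is TargetKind.VALUE_SET_REF:
        members = sorted(schema.value_set_members(t.target_iri))
        return "[ " + " ".join(f"<{m}>" for m in members) + " ]"
    # CLASS_REF: the object may be an instance of the target or any
    # descendant, each validated against its own (closed) shape.
    alts = [t.target_iri] + sorted(schema.descendants(t.target_iri))
    expr = " OR ".join(f"@<{iri}>" for iri in alts)
    return f"( {expr} )" if len(alts) > 1 else expr


def _list_shapes(schema: Schema, cls: ClassDef, prop: PropertyDef) -> list:
    """Auxiliary shapes describing a well-formed RDF collection whose
    elements satisfy the property's target."""
    elem = _value_expr(schema, prop)
    label = f"{cls.iri}.{prop.name}.list"
    shapes = [
        f"<{label}> [ rdf:nil ] OR CLOSED {{\n"
        f"  rdf:first {elem} ;\n"
        f"  rdf:rest @<{label}>\n}}"
    ]
    if prop.multiplicity.min == 1:
        shapes.append(
            f"<{label}.nonempty> CLOSED {{\n"
            f"  rdf:first {elem} ;\n"
            f"  rdf:rest @<{label}>\n}}"
        )
    return shapes


def emit_shex(schema: Schema) -> GeneratedArtifact:
    """Emit the full ShExC schema for ``schema``: one closed shape per
    class (labelled by the class IRI), carrying its flattened properties."""
    out = [
        "# ShEx schema generated from the ontology definition.",
        "# Shapes are CLOSED with EXTRA rdf:type; shape labels are class IRIs.",
        "# '=' (ordered) properties point at RDF-collection shapes; '~' (numbered)",
        "# properties point at an rdf:_1..rdf:_n container, whose numbering is",
        "# checked by the toolchain's own validator rather than by ShEx.",
        f"PREFIX rdf: <{RDF_NS}>",
        f"PREFIX xsd: <{XSD_NS}>",
        "",
    ]
    aux: list = []
    for iri in sorted(schema.classes):
        cls = schema.classes[iri]
        lines = [f"<{iri}> EXTRA rdf:type CLOSED {{",
                 f"  rdf:type [ <{iri}> ] ;"]
        for prop in schema.effective_properties(iri):
            kind = prop.multiplicity.ordered_kind
            if kind is OrderedKind.ORDERED_LIST:
                aux.extend(_list_shapes(schema, cls, prop))
                label = f"{cls.iri}.{prop.name}.list"
                if prop.multiplicity.min == 1:
                    lines.append(f"  <{prop.iri}> @<{label}.nonempty> ;")
                else:
                    lines.append(f"  <{prop.iri}> @<{label}> ? ;")
            elif kind is OrderedKind.NUMBERED_LIST:
                card = "" if prop.multiplicity.min == 1 else " ?"
                lines.append(f"  <{prop.iri}> .{card} ;")
            else:
                card = _CARDINALITY[(prop.multiplicity.min, prop.multiplicity.unbounded)]
                expr = _value_expr(schema, prop)
                lines.append(f"  <{prop.iri}> {expr}{card} ;")
        lines[-1] = lines[-1].removesuffix(" ;")
        lines.append("}")
        out.append("\n".join(lines))
        out.append("")
    out.extend(aux)
    return GeneratedArtifact(kind="shex", path="schema.shex",
                             content="\n".join(out).rstrip() + "\n")
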