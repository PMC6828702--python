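"""Read and write the combined OWL + simplified-ShEx definition format.

The definition file is an ordinary RDF graph (Turtle or RDF/XML), editable
in any OWL editor: classes are ``owl:Class`` nodes linked with
``rdfs:subClassOf``, value sets are subtrees under the ``EnumeratedValue``
class, and each class carries its properties as a *plain-literal*
annotation named ``propertyDefinitions`` written in a small line-oriented
dialect::

    # a comment line becomes the description of the next property
    sequence xsd:string 1..1
    regulatoryClass @RegulatoryClass 1..1
    memberRegions Region =1..N
    xref IRI 0..N

One property per line: ``<name> <target> <multiplicity>``.  Targets are
``xsd:<datatype>`` (primitive), a class name (reference into the schema),
``@Name`` (value set), ``<http://...>`` or the bare token ``IRI``
(external reference).  Multiplicities are ``0..1``, ``1..1``, ``0..N`` or
``1..N``, optionally prefixed with ``=`` (ordered list) or ``~``
(numbered list).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef
from rdflib.namespace import SKOS, XSD

from .errors import (
    DialectSyntaxError,
    DuplicateProperty,
    InputError,
    SchemaError,
)
from .model import (
    AnnotationSet,
    ClassDef,
    Multiplicity,
    OrderedKind,
    PRIMITIVE_DATATYPES,
    PropertyDef,
    Schema,
    TargetRef,
    UNBOUNDED,
    ValueSetDef,
)

#: Local names (under the schema's base IRI) of the reserved vocabulary.
PROPERTY_DEFINITIONS = "propertyDefinitions"
ENUMERATED_VALUE = "EnumeratedValue"
DDBJ_LABEL = "ddbjLabel"

_MULTIPLICITY_TOKENS = {
    "0..1": (0, 1),
    "1..1": (1, 1),
    "0..N": (0, UNBOUNDED),
    "1..N": (1, UNBOUNDED),
}


def parse_multiplicity(token: str) -> Multiplicity:
    """Parse one multiplicity token (``1..N``, ``=0..N``, ``~1..N`` ...).

    Anything outside the four legal forms — including list markers on a
    single-valued multiplicity — raises :class:`DialectSyntaxError`.
    """
    if not token:
        raise DialectSyntaxError("empty multiplicity token")
    kind = OrderedKind.NONE
    body = token
    if token[0] == "=":
        kind, body = OrderedKind.ORDERED_LIST, token[1:]
    elif token[0] == "~":
        kind, body = OrderedKind.NUMBERED_LIST, token[1:]
    if body not in _MULTIPLICITY_TOKENS:
        raise DialectSyntaxError(f"unknown multiplicity token {token!r}")
    lo, hi = _MULTIPLICITY_TOKENS[body]
    if kind is not OrderedKind.NONE and hi is not UNBOUNDED:
        raise DialectSyntaxError(
            f"list marker {token[0]!r} is only valid on unbounded multiplicities ({token!r})"
        )
    return Multiplicity(lo, hi, kind)


def parse_target(token: str, prefixes: Mapping[str, str], base_iri: str) -> TargetRef:
    """Parse one target token of the dialect into a :class:`TargetRef`."""
    if not token:
        raise DialectSyntaxError("empty target token")
    if token == "IRI":
        return TargetRef.external()
    if token.startswith("<") and token.endswith(">"):
        iri = token[1:-1]
        if "://" not in iri and not iri.startswith("urn:"):
            raise DialectSyntaxError(f"external target {token!r} is not an absolute IRI")
        return TargetRef.external(iri)
    if token.startswith("xsd:"):
        name = token[4:]
        if name not in PRIMITIVE_DATATYPES:
            raise DialectSyntaxError(f"unknown primitive datatype {token!r}")
        return TargetRef.primitive(name)
    is_value_set = token.startswith("@")
    name = token[1:] if is_value_set else token
    if ":" in name:
        prefix, local = name.split(":", 1)
        if prefix not in prefixes:
            raise DialectSyntaxError(f"unknown prefix {prefix!r} in target {token!r}")
        iri = prefixes[prefix] + local
    else:
        iri = base_iri + name
    return TargetRef.value_set(iri) if is_value_set else TargetRef.class_ref(iri)


def parse_property_block(
    text: str,
    prefixes: Mapping[str, str],
    base_iri: str,
    class_iri: Optional[str] = None,
) -> list:
    """Parse the full ``propertyDefinitions`` annotation value of one class.

    Returns one :class:`PropertyDef` per non-comment line, in file order;
    ``#`` comment lines attach to the immediately following property as
    its description.  Errors carry the owning class IRI and the 1-based
    line number.
    """
    props: list = []
    seen: set = set()
    pending_comment: list = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            pending_comment = []
            continue
        if line.startswith("#"):
            pending_comment.append(line[1:].strip())
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise DialectSyntaxError(
                f"expected '<name> <target> <multiplicity>', got {line!r}",
                class_iri=class_iri, line=lineno,
            )
        name, target_tok, mult_tok = tokens
        if name in seen:
            raise DuplicateProperty(
                f"property {name!r} defined twice in block of <{class_iri}>"
            )
        try:
            target = parse_target(target_tok, prefixes, base_iri)
            mult = parse_multiplicity(mult_tok)
            prop = PropertyDef(
                name=name,
                iri=base_iri + name,
                target=target,
                multiplicity=mult,
                description=" ".join(pending_comment) if pending_comment else None,
            )
        except DialectSyntaxError as exc:
            raise DialectSyntaxError(str(exc.args[0]), class_iri=class_iri,
                                     line=lineno) from None
        except SchemaError as exc:
            raise DialectSyntaxError(str(exc), class_iri=class_iri, line=lineno) from None
        props.append(prop)
        seen.add(name)
        pending_comment = []
    return props


# ---------------------------------------------------------------------------
# graph -> Schema


def _local_name(iri: str, base_iri: str) -> str:
    if iri.startswith(base_iri):
        return iri[len(base_iri):]
    tail = iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
    return tail


def _opt_literal(graph: Graph, subject: URIRef, predicate) -> Optional[str]:
    value = graph.value(subject, predicate)
    return str(value) if value is not None else None


def parse_schema(source: Union[Graph, str, Path]) -> Schema:
    """Parse a definition graph (or a path to one) into a :class:`Schema`.

    The graph must contain exactly one ``owl:Ontology`` subject, whose IRI
    is taken as the schema's base namespace.
    """
    if isinstance(source, Graph):
        graph = source
    else:
        path = Path(source)
        if not path.exists():
            raise InputError(f"no such schema file: {path}")
        graph = Graph(bind_namespaces="core")
        fmt = "xml" if path.suffix.lower() in {".rdf", ".owl", ".xml"} else "turtle"
        try:
            graph.parse(str(path), format=fmt)
        except Exception as exc:
            raise InputError(f"cannot parse {path}: {exc}") from None

    ontologies = sorted(set(graph.subjects(RDF.type, OWL.Ontology)))
    if len(ontologies) != 1:
        raise InputError(
            f"definition graph must declare exactly one owl:Ontology, found {len(ontologies)}"
        )
    base_iri = str(ontologies[0])
    ns = Namespace(base_iri)
    prefixes = {p: str(n) for p, n in graph.namespaces() if p != "xml"}

    class_iris = {str(s) for s in graph.subjects(RDF.type, OWL.Class)
                  if isinstance(s, URIRef)}

    # Parent map from rdfs:subClassOf (IRI objects only; restriction
    # blank nodes in full OWL output are ignored by design).
    parent: dict = {}
    for iri in class_iris:
        supers = [str(o) for o in graph.objects(URIRef(iri), RDFS.subClassOf)
                  if isinstance(o, URIRef) and str(o) in class_iris]
        if len(supers) > 1:
            raise SchemaError(f"<{iri}> has multiple parents: {sorted(supers)}")
        parent[iri] = supers[0] if supers else None

    # Cycle check before any tree walk.
    for start in class_iris:
        seen = {start}
        cur = parent.get(start)
        while cur is not None:
            if cur in seen:
                from .errors import CyclicHierarchy
                raise CyclicHierarchy(f"rdfs:subClassOf cycle through <{cur}>")
            seen.add(cur)
            cur = parent.get(cur)

    # Value sets: subtree under <base>EnumeratedValue.
    ev_iri = base_iri + ENUMERATED_VALUE
    children: dict = {}
    for iri, par in parent.items():
        if par is not None:
            children.setdefault(par, []).append(iri)

    value_sets: dict = {}
    ev_subtree: set = {ev_iri} if ev_iri in class_iris else set()
    for vs_iri in sorted(children.get(ev_iri, [])):
        members: dict = {}
        frontier = [(m, None) for m in sorted(children.get(vs_iri, []))]
        while frontier:
            member, member_parent = frontier.pop(0)
            members[member] = member_parent
            frontier.extend((m, member) for m in sorted(children.get(member, [])))
        name = _local_name(vs_iri, base_iri)
        definition = (_opt_literal(graph, URIRef(vs_iri), SKOS.definition)
                      or _opt_literal(graph, URIRef(vs_iri), RDFS.label) or name)
        annotations = AnnotationSet(
            definition=definition,
            usage_comment=_opt_literal(graph, URIRef(vs_iri), SKOS.scopeNote),
            editorial_comment=_opt_literal(graph, URIRef(vs_iri), SKOS.editorialNote),
            ddbj_label=_opt_literal(graph, URIRef(vs_iri), ns[DDBJ_LABEL]),
            exact_matches=frozenset(
                str(o) for o in graph.objects(URIRef(vs_iri), SKOS.exactMatch)
            ),
        )
        value_sets[vs_iri] = ValueSetDef(iri=vs_iri, name=name, members=members,
                                         annotations=annotations)
        ev_subtree |= {vs_iri} | set(members)

    # Ordinary classes: everything else but the EnumeratedValue subtree.
    classes: dict = {}
    prop_def_pred = ns[PROPERTY_DEFINITIONS]
    for iri in sorted(class_iris - ev_subtree):
        subject = URIRef(iri)
        name = _local_name(iri, base_iri)
        definition = (_opt_literal(graph, subject, SKOS.definition)
                      or _opt_literal(graph, subject, RDFS.label) or name)
        annotations = AnnotationSet(
            definition=definition,
            usage_comment=_opt_literal(graph, subject, SKOS.scopeNote),
            editorial_comment=_opt_literal(graph, subject, SKOS.editorialNote),
            ddbj_label=_opt_literal(graph, subject, ns[DDBJ_LABEL]),
            exact_matches=frozenset(
                str(o) for o in graph.objects(subject, SKOS.exactMatch)
            ),
        )
        block = graph.value(subject, prop_def_pred)
        properties = ()
        if block is not None:
            properties = tuple(
                parse_property_block(str(block), prefixes, base_iri, class_iri=iri)
            )
        classes[iri] = ClassDef(iri=iri, name=name, annotations=annotations,
                                parent=parent[iri], properties=properties)

    return Schema(base_iri=base_iri, classes=classes, value_sets=value_sets,
                  prefixes=prefixes)


# ---------------------------------------------------------------------------
# Schema -> definition file


_STANDARD_PREFIXES = (
    ("owl", "http://www.w3.org/2002/07/owl#"),
    ("rdf", "http://www.w3.org/1999/02/22-rdf-syntax-ns#"),
    ("rdfs", "http://www.w3.org/2000/01/rdf-schema#"),
    ("skos", "http://www.w3.org/2004/02/skos/core#"),
    ("xsd", "http://www.w3.org/2001/XMLSchema#"),
)


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _format_block(schema: Schema, cls: ClassDef) -> str:
    lines = []
    for prop in cls.properties:
        if prop.description:
            lines.append(f"# {prop.description}")
        lines.append(f"{prop.name} {_target_token(schema, prop)} "
                     f"{prop.multiplicity.token()}")
    return "\n".join(lines)


def _target_token(schema: Schema, prop: PropertyDef) -> str:
    t = prop.target
    from .model import ANY_IRI, TargetKind
    if t.kind is TargetKind.PRIMITIVE:
        return f"xsd:{t.datatype}"
    if t.kind is TargetKind.EXTERNAL_IRI:
        return "IRI" if t.target_iri == ANY_IRI else f"<{t.target_iri}>"
    if not t.target_iri.startswith(schema.base_iri):
        for prefix, nsiri in sorted(schema.prefixes.items()):
            if nsiri and t.target_iri.startswith(nsiri):
                local = t.target_iri[len(nsiri):]
                return ("@" if t.kind is TargetKind.VALUE_SET_REF else "") + f"{prefix}:{local}"
        raise SchemaError(
            f"cannot emit target <{t.target_iri}>: outside the base namespace "
            f"and no declared prefix covers it"
        )
    local = t.target_iri[len(schema.base_iri):]
    return ("@" + local) if t.kind is TargetKind.VALUE_SET_REF else local


def _annotation_lines(schema: Schema, ann: AnnotationSet) -> list:
    out = [f'    skos:definition "{_escape(ann.definition)}" ;']
    if ann.usage_comment:
        out.append(f'    skos:scopeNote "{_escape(ann.usage_comment)}" ;')
    if ann.editorial_comment:
        out.append(f'    skos:editorialNote "{_escape(ann.editorial_comment)}" ;')
    if ann.ddbj_label:
        out.append(f'    <{schema.base_iri}{DDBJ_LABEL}> "{_escape(ann.ddbj_label)}" ;')
    for match in sorted(ann.exact_matches):
        out.append(f"    skos:exactMatch <{match}> ;")
    return out


def emit_definition(schema: Schema) -> str:
    """Serialize a :class:`Schema` back to the Turtle definition format.

    Output is deterministic (classes, value sets and annotation triples
    sorted by IRI; property lines in their defined order) so that an
    unchanged schema re-emits byte-identically, and
    ``parse_schema(emit_definition(s))`` reconstructs ``s``.
    """
    base = schema.base_iri
    lines: list = []
    for prefix, nsiri in _STANDARD_PREFIXES:
        lines.append(f"@prefix {prefix}: <{nsiri}> .")
    standard = {p for p, _ in _STANDARD_PREFIXES}
    for prefix, nsiri in sorted(schema.prefixes.items()):
        if prefix and prefix not in standard and nsiri not in dict(_STANDARD_PREFIXES).values():
            lines.append(f"@prefix {prefix}: <{nsiri}> .")
    lines.append("")
    lines.append(f"<{base}> a owl:Ontology .")
    lines.append("")
    lines.append(f"<{base}{PROPERTY_DEFINITIONS}> a owl:AnnotationProperty ;")
    lines.append('    rdfs:label "propertyDefinitions" .')
    lines.append(f"<{base}{DDBJ_LABEL}> a owl:AnnotationProperty ;")
    lines.append('    rdfs:label "ddbjLabel" .')
    lines.append("")

    for iri in sorted(schema.classes):
        cls = schema.classes[iri]
        lines.append(f"<{iri}> a owl:Class ;")
        if cls.parent is not None:
            lines.append(f"    rdfs:subClassOf <{cls.parent}> ;")
        lines.append(f'    rdfs:label "{_escape(cls.name)}" ;')
        lines.extend(_annotation_lines(schema, cls.annotations))
        block = _format_block(schema, cls)
        if block:
            lines.append(f'    <{base}{PROPERTY_DEFINITIONS}> "{_escape_block(block)}" ;')
        lines[-1] = lines[-1].removesuffix(" ;") + " ."
        lines.append("")

    if schema.value_sets:
        lines.append(f"<{base}{ENUMERATED_VALUE}> a owl:Class ;")
        lines.append('    skos:definition "Root class under which all value sets are defined." .')
        lines.append("")
        for vs_iri in sorted(schema.value_sets):
            vs = schema.value_sets[vs_iri]
            lines.append(f"<{vs_iri}> a owl:Class ;")
            lines.append(f"    rdfs:subClassOf <{base}{ENUMERATED_VALUE}> ;")
            lines.append(f'    rdfs:label "{_escape(vs.name)}" ;')
            if vs.annotations is not None:
                lines.extend(_annotation_lines(schema, vs.annotations))
            lines[-1] = lines[-1].removesuffix(" ;") + " ."
            for member in sorted(vs.members):
                par = vs.members[member] or vs_iri
                lines.append(f"<{member}> a owl:Class ; rdfs:subClassOf <{par}> .")
            lines.append("")

    return "\n".join(lines).rstrip() + "\n"


def _escape_block(block: str) -> str:
    # propertyDefinitions blocks are emitted as single-quoted literals with
    # explicit \n escapes; round-trips through any Turtle parser.
    return _escape(block).replace("\n", "\\n")
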