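"""Closed-world conformance checking of RDF instance data against a Schema.

Unlike OWL's open-world reading — where a missing obligatory link is
merely "not yet known" — every typed subject here is checked against the
complete, flattened property list of its class: required links must be
present, cardinalities must hold, referenced objects must carry a
compatible type, value-set properties must use member IRIs, and any
predicate outside the class's property list (other than ``rdf:type``)
is an error.  Problems are reported as :class:`Violation` records of
eight structural kinds, never as exceptions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD

from .errors import InputError
from .model import OrderedKind, PropertyDef, Schema, TargetKind
from .reader import ENUMERATED_VALUE

_RDF_MEMBER_RE = re.compile(
    re.escape("http://www.w3.org/1999/02/22-rdf-syntax-ns#_") + r"(\d+)$"
)


class ViolationKind(Enum):
    UNKNOWN_PREDICATE = "unknown_predicate"
    MISSING_REQUIRED = "missing_required"
    CARDINALITY_EXCEEDED = "cardinality_exceeded"
    WRONG_TARGET_TYPE = "wrong_target_type"
    UNTYPED_NODE = "untyped_node"
    VALUE_SET_VIOLATION = "value_set_violation"
    MALFORMED_LIST = "malformed_list"
    NON_SCHEMA_TYPE = "non_schema_type"
    # Semantic add-on used by domain-specific rule checks (e.g. the
    # strand-on-unstranded-sequence rule); not part of the structural
    # taxonomy above and never produced by validate_graph itself.
    STRAND_RULE = "strand_rule"


#: The eight structural kinds detected by :func:`validate_graph`.
STRUCTURAL_KINDS = tuple(k for k in ViolationKind if k is not ViolationKind.STRAND_RULE)


@dataclass(frozen=True)
class Violation:
    kind: ViolationKind
    subject: str
    predicate: Optional[str] = None
    detail: str = ""

    def key(self):
        return (self.kind.value, self.subject, self.predicate or "")


@dataclass
class ValidationReport:
    violations: list
    checked_instances: int
    warnings: list

    @property
    def conforms(self) -> bool:
        return not self.violations

    def kinds(self) -> frozenset:
        return frozenset(v.kind for v in self.violations)

    def to_json(self) -> str:
        return json.dumps(
            {
                "conforms": self.conforms,
                "checked_instances": self.checked_instances,
                "violations": [
                    {"kind": v.kind.value, "subject": v.subject,
                     "predicate": v.predicate, "detail": v.detail}
                    for v in self.violations
                ],
                "warnings": self.warnings,
            },
            indent=2,
        )

    def to_text(self) -> str:
        if self.conforms:
            return (f"conforms: {self.checked_instances} instance(s) checked, "
                    f"0 violations\n")
        lines = [f"does NOT conform: {len(self.violations)} violation(s) over "
                 f"{self.checked_instances} checked instance(s)"]
        for v in self.violations:
            where = f" [{v.predicate}]" if v.predicate else ""
            lines.append(f"  {v.kind.value:22s} {v.subject}{where}  {v.detail}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------


def _typed_map(graph: Graph) -> dict:
    typed: dict = {}
    for subject, type_iri in graph.subject_objects(RDF.type):
        typed.setdefault(subject, set()).add(type_iri)
    return typed


def _walk_collection(graph: Graph, head):
    """Walk an rdf:first/rdf:rest chain; returns (elements, error or None)."""
    elements: list = []
    seen: set = set()
    cur = head
    while cur != RDF.nil:
        if isinstance(cur, Literal):
            return elements, "rdf:rest chain reaches a literal"
        if cur in seen:
            return elements, "cyclic rdf:rest chain"
        seen.add(cur)
        firsts = list(graph.objects(cur, RDF.first))
        rests = list(graph.objects(cur, RDF.rest))
        if len(firsts) != 1 or len(rests) != 1:
            return elements, ("collection node needs exactly one rdf:first "
                              "and one rdf:rest")
        elements.append(firsts[0])
        cur = rests[0]
    return elements, None


def _walk_container(graph: Graph, head):
    """Collect rdf:_1..rdf:_n members; returns (elements, error or None)."""
    if isinstance(head, Literal):
        return None, "container must be a node, not a literal"
    members: dict = {}
    for pred, obj in graph.predicate_objects(head):
        match = _RDF_MEMBER_RE.match(str(pred))
        if match:
            index = int(match.group(1))
            if index in members:
                return None, f"duplicate membership property rdf:_{index}"
            members[index] = obj
        elif pred == RDF.type:
            continue
        else:
            return None, f"unexpected predicate <{pred}> on container node"
    if sorted(members) != list(range(1, len(members) + 1)):
        return None, "membership properties are not numbered contiguously from rdf:_1"
    return [members[i] for i in sorted(members)], None


_NUMERIC_LEXICAL = {
    "integer": re.compile(r"^[+-]?\d+$"),
    "double": re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$"),
    "boolean": re.compile(r"^(true|false|0|1)$"),
    "anyURI": re.compile(r"^\S+$"),
}


class _Checker:
    def __init__(self, graph: Graph, schema: Schema, typed: dict):
        self.graph = graph
        self.schema = schema
        self.typed = typed
        self.violations: list = []
        self.warnings: list = []

    def add(self, kind: ViolationKind, subject, predicate=None, detail: str = ""):
        self.violations.append(
            Violation(kind, str(subject),
                      str(predicate) if predicate is not None else None, detail)
        )

    # -- value-level checks -------------------------------------------------

    def check_value(self, subject, prop: PropertyDef, obj) -> None:
        target = prop.target
        if target.kind is TargetKind.PRIMITIVE:
            self._check_literal(subject, prop, obj)
        elif target.kind is TargetKind.CLASS_REF:
            if isinstance(obj, Literal):
                self.add(ViolationKind.WRONG_TARGET_TYPE, subject, prop.iri,
                         f"literal where an instance of <{target.target_iri}> "
                         f"is required")
                return
            types = {str(t) for t in self.typed.get(obj, set())}
            if not types:
                self.add(ViolationKind.UNTYPED_NODE, obj, prop.iri,
                         f"referenced by <{subject}> but carries no rdf:type")
                return
            compatible = any(
                t in self.schema.classes
                and self.schema.is_subclass_of(t, target.target_iri)
                for t in types
            )
            if not compatible:
                self.add(ViolationKind.WRONG_TARGET_TYPE, subject, prop.iri,
                         f"<{obj}> is typed {sorted(types)}, expected "
                         f"<{target.target_iri}> or a descendant")
        elif target.kind is TargetKind.VALUE_SET_REF:
            members = self.schema.value_set_members(target.target_iri)
            if not isinstance(obj, URIRef) or str(obj) not in members:
                self.add(ViolationKind.VALUE_SET_VIOLATION, subject, prop.iri,
                         f"{obj} is not a member of <{target.target_iri}>")
        else:  # EXTERNAL_IRI: syntactic check only, never dereferenced
            if not isinstance(obj, URIRef) or (
                    "://" not in str(obj) and not str(obj).startswith("urn:")):
                self.add(ViolationKind.WRONG_TARGET_TYPE, subject, prop.iri,
                         f"{obj} is not an absolute IRI")

    def _check_literal(self, subject, prop: PropertyDef, obj) -> None:
        if not isinstance(obj, Literal):
            self.add(ViolationKind.WRONG_TARGET_TYPE, subject, prop.iri,
                     f"expected an xsd:{prop.target.datatype} literal, got {obj}")
            return
        datatype = prop.target.datatype
        if datatype == "string":
            if obj.datatype is not None and str(obj.datatype) != str(XSD.string) \
                    and str(obj.datatype) != str(RDF.langString):
                self.add(ViolationKind.WRONG_TARGET_TYPE, subject, prop.iri,
                         f"literal typed <{obj.datatype}> where xsd:string expected")
            return
        expected = prop.target.datatype_iri
        if obj.datatype is None:
            # plain literal against a non-string target: tolerated when the
            # lexical form is valid, but flagged for the producer to fix
            if _NUMERIC_LEXICAL[datatype].match(str(obj)):
                self.warnings.append(
                    f"<{subject}> <{prop.iri}>: untyped literal {str(obj)!r} "
                    f"accepted for xsd:{datatype}"
                )
            else:
                self.add(ViolationKind.WRONG_TARGET_TYPE, subject, prop.iri,
                         f"{str(obj)!r} is not a valid xsd:{datatype}")
        elif str(obj.datatype) != expected:
            self.add(ViolationKind.WRONG_TARGET_TYPE, subject, prop.iri,
                     f"literal typed <{obj.datatype}> where xsd:{datatype} expected")

    # -- instance-level check -----------------------------------------------

    def check_instance(self, node, class_iri: str) -> None:
        if class_iri not in self.schema.classes:
            self.add(ViolationKind.NON_SCHEMA_TYPE, node, None,
                     f"rdf:type <{class_iri}> is not a class of the schema")
            return
        props = {p.iri: p for p in self.schema.effective_properties(class_iri)}

        outgoing: dict = {}
        for pred, obj in self.graph.predicate_objects(node):
            outgoing.setdefault(str(pred), []).append(obj)
        outgoing.pop(str(RDF.type), None)

        for pred in outgoing:
            if pred not in props:
                self.add(ViolationKind.UNKNOWN_PREDICATE, node, pred,
                         f"not a property of <{class_iri}> (closed world)")

        for iri, prop in props.items():
            objects = outgoing.get(iri, [])
            kind = prop.multiplicity.ordered_kind
            if kind is OrderedKind.NONE:
                self._check_plain(node, prop, objects)
            else:
                self._check_list(node, prop, objects, kind)

    def _check_plain(self, node, prop: PropertyDef, objects: list) -> None:
        count = len(objects)
        if count < prop.multiplicity.min:
            self.add(ViolationKind.MISSING_REQUIRED, node, prop.iri,
                     "required property absent")
        if not prop.multiplicity.unbounded and count > 1:
            self.add(ViolationKind.CARDINALITY_EXCEEDED, node, prop.iri,
                     f"{count} values where at most one is allowed")
        for obj in objects:
            self.check_value(node, prop, obj)

    def _check_list(self, node, prop: PropertyDef, objects: list,
                    kind: OrderedKind) -> None:
        if len(objects) > 1:
            self.add(ViolationKind.CARDINALITY_EXCEEDED, node, prop.iri,
                     f"{len(objects)} list heads where one is expected")
            return
        if not objects:
            if prop.multiplicity.min == 1:
                self.add(ViolationKind.MISSING_REQUIRED, node, prop.iri,
                         "required list property absent")
            return
        head = objects[0]
        if kind is OrderedKind.ORDERED_LIST:
            elements, error = _walk_collection(self.graph, head)
        else:
            elements, error = _walk_container(self.graph, head)
        if error is not None:
            self.add(ViolationKind.MALFORMED_LIST, node, prop.iri, error)
            return
        if len(elements) < prop.multiplicity.min:
            self.add(ViolationKind.MISSING_REQUIRED, node, prop.iri,
                     "list present but empty where at least one element is required")
        for element in elements:
            self.check_value(node, prop, element)


# ---------------------------------------------------------------------------
# public entry points


def _as_graph(data: Union[Graph, str, Path]) -> Graph:
    if isinstance(data, Graph):
        return data
    path = Path(data)
    if not path.exists():
        raise InputError(f"no such data file: {path}")
    graph = Graph(bind_namespaces="core")
    try:
        graph.parse(str(path), format="turtle")
    except Exception as exc:
        raise InputError(f"cannot parse {path}: {exc}") from None
    return graph


def _dedup(violations: list) -> list:
    seen: set = set()
    out: list = []
    for v in sorted(violations, key=lambda v: v.key()):
        if v.key() not in seen:
            seen.add(v.key())
            out.append(v)
    return out


def check_instance(node, class_iri: str, data: Union[Graph, str, Path],
                   schema: Schema) -> list:
    """Violations attributable to one typed subject (deduplicated)."""
    graph = _as_graph(data)
    checker = _Checker(graph, schema, _typed_map(graph))
    subject = node if isinstance(node, (URIRef, BNode)) else URIRef(node)
    checker.check_instance(subject, class_iri)
    return _dedup(checker.violations)


def validate_graph(data: Union[Graph, str, Path], schema: Schema) -> ValidationReport:
    """Check every typed subject of ``data`` against ``schema``.

    Subjects typed with a schema class are validated under the
    closed-world interpretation; subjects typed with an unknown IRI
    *inside* the schema namespace are reported as NON_SCHEMA_TYPE;
    types from foreign namespaces are ignored (they belong to other
    ontologies and cannot be closed-world checked locally).
    """
    graph = _as_graph(data)
    typed = _typed_map(graph)
    checker = _Checker(graph, schema, typed)

    vocabulary_iris = {schema.base_iri + ENUMERATED_VALUE}
    for vs in schema.value_sets.values():
        vocabulary_iris.add(vs.iri)
        vocabulary_iris.update(vs.members)

    checked = 0
    for node in sorted(typed, key=str):
        for type_iri in sorted(typed[node], key=str):
            iri = str(type_iri)
            if iri in schema.classes:
                checker.check_instance(node, iri)
                checked += 1
            elif iri in vocabulary_iris:
                continue  # value vocabulary, not instance classes
            elif iri.startswith(schema.base_iri):
                checker.add(ViolationKind.NON_SCHEMA_TYPE, node, None,
                            f"rdf:type <{iri}> is not a class of the schema")
    return ValidationReport(violations=_dedup(checker.violations),
                            checked_instances=checked,
                            warnings=checker.warnings)
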