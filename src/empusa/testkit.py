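"""Synthetic schemas, conforming instance graphs and seeded single-fault
mutations.

This is the verification harness for the whole toolchain: random schemas
exercise every target kind and multiplicity form; the instance generator
produces graphs the validator must accept; and :func:`mutate` corrupts a
conforming graph with the *minimal* edit inducing exactly one violation
kind, so detection can be checked for completeness (every seeded fault
found) and specificity (no other kinds reported, zero false positives on
the unmutated graph).

All randomness flows through one ``random.Random(seed)`` per call; equal
seeds give identical output.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass
from typing import Optional

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD

from .errors import NotApplicable
from .model import (
    AnnotationSet,
    ClassDef,
    Multiplicity,
    OrderedKind,
    PropertyDef,
    Schema,
    TargetKind,
    TargetRef,
    UNBOUNDED,
    ValueSetDef,
)
from .validate import ViolationKind

_MULTIPLICITIES = (
    Multiplicity(0, 1),
    Multiplicity(1, 1),
    Multiplicity(0, UNBOUNDED),
    Multiplicity(1, UNBOUNDED),
)
_PRIMITIVES = ("string", "integer", "double", "boolean", "anyURI")


# ---------------------------------------------------------------------------
# random schemas


def random_schema(seed: int, n_classes: int, n_value_sets: int = 1) -> Schema:
    """A valid random schema: tree hierarchy, properties over all target
    kinds and all four multiplicities, optional list markers."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    rng = random.Random(seed)
    base = f"http://example.org/schema{seed}/"

    value_sets = {}
    for j in range(n_value_sets):
        name = f"Set{j}"
        members: dict = {}
        for k in range(rng.randint(2, 4)):
            member = f"{base}{name}Member{k}"
            parent = None
            if k > 0 and rng.random() < 0.3:
                parent = rng.choice(sorted(members))
            members[member] = parent
        value_sets[base + name] = ValueSetDef(
            iri=base + name, name=name, members=members,
            annotations=AnnotationSet(definition=f"Value set {name}."))

    names = [f"Class{i}" for i in range(n_classes)]
    iris = [base + n for n in names]
    parents: list = [None]
    for i in range(1, n_classes):
        parents.append(rng.choice(iris[:i]) if rng.random() < 0.5 else None)

    prop_counter = 0
    classes: dict = {}
    for i, name in enumerate(names):
        props = []
        for _ in range(rng.randint(0, 3)):
            prop_name = f"prop{prop_counter}"
            prop_counter += 1
            kind = rng.choices(
                ("primitive", "class", "value_set", "external"),
                weights=(4, 3, 2, 1))[0]
            if kind == "primitive":
                target = TargetRef.primitive(rng.choice(_PRIMITIVES))
            elif kind == "class":
                target = TargetRef.class_ref(rng.choice(iris))
            elif kind == "value_set" and value_sets:
                target = TargetRef.value_set(rng.choice(sorted(value_sets)))
            else:
                target = TargetRef.external()
            mult = rng.choice(_MULTIPLICITIES)
            if mult.unbounded and rng.random() < 0.4:
                mult = Multiplicity(mult.min, UNBOUNDED,
                                    rng.choice((OrderedKind.ORDERED_LIST,
                                                OrderedKind.NUMBERED_LIST)))
            props.append(PropertyDef(
                name=prop_name, iri=base + prop_name, target=target,
                multiplicity=mult,
                description=f"Random property {prop_name}."
                if rng.random() < 0.7 else None))
        classes[iris[i]] = ClassDef(
            iri=iris[i], name=name, parent=parents[i], properties=tuple(props),
            annotations=AnnotationSet(definition=f"Random class {name}."))

    return Schema(base_iri=base, classes=classes, value_sets=value_sets)


# ---------------------------------------------------------------------------
# conforming instance graphs


class _InstanceBuilder:
    def __init__(self, schema: Schema, rng: random.Random, graph: Graph):
        self.schema = schema
        self.rng = rng
        self.graph = graph
        self.instances: dict = {}   # class iri -> [nodes]
        self.pending: deque = deque()
        self.node_counter = 0
        self.bnode_counter = 0
        self.ext_counter = 0

    def bnode(self) -> BNode:
        self.bnode_counter += 1
        return BNode(f"b{self.bnode_counter}")

    def new_instance(self, class_iri: str):
        self.node_counter += 1
        node = URIRef(f"{self.schema.base_iri}data/i{self.node_counter}")
        self.graph.add((node, RDF.type, URIRef(class_iri)))
        self.instances.setdefault(class_iri, []).append(node)
        self.pending.append((node, class_iri))
        return node

    def _concrete_target(self, target_iri: str) -> str:
        options = [target_iri] + sorted(self.schema.descendants(target_iri))
        return self.rng.choice(options)

    def object_for(self, target: TargetRef):
        if target.kind is TargetKind.PRIMITIVE:
            return self.literal(target.datatype)
        if target.kind is TargetKind.VALUE_SET_REF:
            members = sorted(self.schema.value_set_members(target.target_iri))
            return URIRef(self.rng.choice(members))
        if target.kind is TargetKind.EXTERNAL_IRI:
            self.ext_counter += 1
            return URIRef(f"http://external.example.org/x{self.ext_counter}")
        # CLASS_REF: reuse a compatible instance when possible
        compatible = [target.target_iri] + sorted(
            self.schema.descendants(target.target_iri))
        existing = [n for c in compatible for n in self.instances.get(c, ())]
        if existing and (self.node_counter > 50 or self.rng.random() < 0.7):
            return self.rng.choice(existing)
        return self.new_instance(self._concrete_target(target.target_iri))

    def literal(self, datatype: str) -> Literal:
        rng = self.rng
        if datatype == "string":
            return Literal("".join(rng.choice("abcdefgh")
                                   for _ in range(rng.randint(3, 8))))
        if datatype == "integer":
            return Literal(rng.randrange(0, 10 ** 6))
        if datatype == "double":
            return Literal(round(rng.uniform(0, 1000), 3))
        if datatype == "boolean":
            return Literal(rng.random() < 0.5)
        return Literal(f"http://external.example.org/u{rng.randrange(10**6)}",
                       datatype=XSD.anyURI)

    def fill(self, node, class_iri: str) -> None:
        for prop in self.schema.effective_properties(class_iri):
            mult = prop.multiplicity
            if mult.min == 0 and self.rng.random() < 0.4:
                continue
            count = 1 if not mult.unbounded else self.rng.randint(max(mult.min, 1), 2)
            kind = mult.ordered_kind
            if kind is OrderedKind.ORDERED_LIST:
                head: object = RDF.nil
                elements = [self.object_for(prop.target) for _ in range(count)]
                for element in reversed(elements):
                    cell = self.bnode()
                    self.graph.add((cell, RDF.first, element))
                    self.graph.add((cell, RDF.rest, head))
                    head = cell
                self.graph.add((node, URIRef(prop.iri), head))
            elif kind is OrderedKind.NUMBERED_LIST:
                container = self.bnode()
                self.graph.add((node, URIRef(prop.iri), container))
                for i in range(count):
                    self.graph.add((container, URIRef(f"{RDF}_{i + 1}"),
                                    self.object_for(prop.target)))
            else:
                for _ in range(count):
                    self.graph.add((node, URIRef(prop.iri),
                                    self.object_for(prop.target)))


def conforming_instances(schema: Schema, seed: int, n_instances: int) -> Graph:
    """A graph of ``n_instances`` randomly typed, fully conforming
    subjects (plus any auxiliary instances needed to satisfy required
    references; reference cycles are handled by allocating nodes before
    linking them)."""
    rng = random.Random(seed)
    graph = Graph(bind_namespaces="core")
    builder = _InstanceBuilder(schema, rng, graph)
    class_iris = sorted(schema.classes)
    for _ in range(n_instances):
        builder.new_instance(rng.choice(class_iris))
    while builder.pending:
        node, class_iri = builder.pending.popleft()
        builder.fill(node, class_iri)
    return graph


# ---------------------------------------------------------------------------
# seeded mutations


@dataclass(frozen=True)
class Mutation:
    kind: ViolationKind
    seed: int
    applied_to: tuple    # (subject, predicate-or-None)
    description: str


def _copy(graph: Graph) -> Graph:
    out = Graph(bind_namespaces="core")
    for triple in graph:
        out.add(triple)
    return out


def _typed_subjects(graph: Graph, schema: Schema) -> list:
    out = []
    for subject, type_iri in sorted(graph.subject_objects(RDF.type),
                                    key=lambda p: (str(p[0]), str(p[1]))):
        if str(type_iri) in schema.classes:
            out.append((subject, str(type_iri)))
    return out


def _prop_map(schema: Schema, class_iri: str) -> dict:
    return {p.iri: p for p in schema.effective_properties(class_iri)}


def mutate(graph: Graph, schema: Schema, kind: ViolationKind, seed: int):
    """Return a corrupted copy of a conforming graph plus the Mutation
    record; the copy yields at least one violation of exactly ``kind``
    and no violations of any other kind.  Raises :class:`NotApplicable`
    when the graph offers no site for the requested kind."""
    rng = random.Random(seed)
    out = _copy(graph)
    subjects = _typed_subjects(out, schema)
    handler = _HANDLERS[kind]
    return handler(out, schema, rng, subjects, seed)


def _pick(rng: random.Random, items: list):
    if not items:
        raise NotApplicable("no candidate site for this mutation kind")
    return rng.choice(items)


def _mut_missing_required(out, schema, rng, subjects, seed):
    candidates = []
    for node, class_iri in subjects:
        for prop in _prop_map(schema, class_iri).values():
            if prop.multiplicity.min == 1 and \
                    (node, URIRef(prop.iri), None) in out:
                candidates.append((node, prop))
    node, prop = _pick(rng, candidates)
    for obj in list(out.objects(node, URIRef(prop.iri))):
        out.remove((node, URIRef(prop.iri), obj))
    return out, Mutation(ViolationKind.MISSING_REQUIRED, seed,
                         (str(node), prop.iri),
                         f"removed required property {prop.name}")


def _mut_cardinality(out, schema, rng, subjects, seed):
    candidates = []
    for node, class_iri in subjects:
        for prop in _prop_map(schema, class_iri).values():
            if prop.multiplicity.unbounded:
                continue
            extra = _extra_value(out, schema, rng, node, prop)
            if extra is not None:
                candidates.append((node, prop, extra))
    node, prop, extra = _pick(rng, candidates)
    out.add((node, URIRef(prop.iri), extra))
    if (node, URIRef(prop.iri), None) not in out:
        raise AssertionError  # pragma: no cover
    return out, Mutation(ViolationKind.CARDINALITY_EXCEEDED, seed,
                         (str(node), prop.iri),
                         f"added a second value for {prop.name}")


def _extra_value(graph, schema, rng, node, prop):
    """A *valid* additional value differing from the current one, or None."""
    current = set(graph.objects(node, URIRef(prop.iri)))
    if len(current) != 1:
        return None
    target = prop.target
    if target.kind is TargetKind.PRIMITIVE:
        builder = _InstanceBuilder(schema, rng, graph)
        for _ in range(10):
            value = builder.literal(target.datatype)
            if value not in current:
                return value
        return None
    if target.kind is TargetKind.VALUE_SET_REF:
        members = sorted(schema.value_set_members(target.target_iri))
        options = [URIRef(m) for m in members if URIRef(m) not in current]
        return rng.choice(options) if options else None
    if target.kind is TargetKind.EXTERNAL_IRI:
        return URIRef("http://external.example.org/extra")
    compatible = {target.target_iri} | schema.descendants(target.target_iri)
    options = [s for s, c in _typed_subjects(graph, schema)
               if c in compatible and s not in current]
    return rng.choice(options) if options else None


def _mut_unknown_predicate(out, schema, rng, subjects, seed):
    candidates = []
    for node, class_iri in subjects:
        props = _prop_map(schema, class_iri)
        known = set(props)
        for prop in props.values():
            objs = list(out.objects(node, URIRef(prop.iri)))
            removable = (prop.multiplicity.min == 0
                         or len(objs) > 1
                         or prop.multiplicity.unbounded and len(objs) > prop.multiplicity.min)
            if objs and removable:
                typo = prop.iri[:-1] if prop.iri[-1] != "x" else prop.iri + "y"
                if typo not in known:
                    candidates.append((node, prop, objs[0], typo))
    node, prop, obj, typo = _pick(rng, candidates)
    out.remove((node, URIRef(prop.iri), obj))
    out.add((node, URIRef(typo), obj))
    return out, Mutation(ViolationKind.UNKNOWN_PREDICATE, seed,
                         (str(node), typo),
                         f"perturbed predicate {prop.name} by one character")


def _mut_wrong_target_type(out, schema, rng, subjects, seed):
    candidates = []
    for node, class_iri in subjects:
        for prop in _prop_map(schema, class_iri).values():
            if prop.multiplicity.ordered_kind is not OrderedKind.NONE:
                continue
            if prop.target.kind is TargetKind.PRIMITIVE:
                for obj in out.objects(node, URIRef(prop.iri)):
                    if prop.target.datatype == "string":
                        bad = Literal("3", datatype=XSD.integer)
                    else:
                        # a wrongly *typed* literal: an untyped one would be
                        # tolerated (warning) when lexically valid
                        bad = Literal("oops", datatype=XSD.string)
                    candidates.append((node, prop, obj, bad))
            elif prop.target.kind is TargetKind.CLASS_REF:
                compatible = {prop.target.target_iri} | \
                    schema.descendants(prop.target.target_iri)
                wrong = [s for s, c in subjects if c not in compatible]
                for obj in out.objects(node, URIRef(prop.iri)):
                    if wrong:
                        candidates.append((node, prop, obj, rng.choice(wrong)))
    node, prop, obj, bad = _pick(rng, candidates)
    out.remove((node, URIRef(prop.iri), obj))
    out.add((node, URIRef(prop.iri), bad))
    return out, Mutation(ViolationKind.WRONG_TARGET_TYPE, seed,
                         (str(node), prop.iri),
                         f"replaced a value of {prop.name} with an "
                         f"incompatible one")


def _mut_untyped_node(out, schema, rng, subjects, seed):
    candidates = []
    for node, class_iri in subjects:
        for prop in _prop_map(schema, class_iri).values():
            if prop.target.kind is not TargetKind.CLASS_REF:
                continue
            if prop.multiplicity.ordered_kind is not OrderedKind.NONE:
                continue
            for obj in out.objects(node, URIRef(prop.iri)):
                if obj != node:  # untyping a self-reference would silence it
                    candidates.append((node, prop, obj))
    node, prop, obj = _pick(rng, candidates)
    for type_iri in list(out.objects(obj, RDF.type)):
        out.remove((obj, RDF.type, type_iri))
    return out, Mutation(ViolationKind.UNTYPED_NODE, seed,
                         (str(obj), prop.iri),
                         "deleted the rdf:type of a referenced object")


def _mut_value_set(out, schema, rng, subjects, seed):
    candidates = []
    for node, class_iri in subjects:
        for prop in _prop_map(schema, class_iri).values():
            if prop.target.kind is not TargetKind.VALUE_SET_REF:
                continue
            if prop.multiplicity.ordered_kind is not OrderedKind.NONE:
                continue
            for obj in out.objects(node, URIRef(prop.iri)):
                candidates.append((node, prop, obj))
    node, prop, obj = _pick(rng, candidates)
    out.remove((node, URIRef(prop.iri), obj))
    out.add((node, URIRef(prop.iri), URIRef(schema.base_iri + "Purple")))
    return out, Mutation(ViolationKind.VALUE_SET_VIOLATION, seed,
                         (str(node), prop.iri),
                         f"replaced a {prop.name} value with a non-member IRI")


def _mut_malformed_list(out, schema, rng, subjects, seed):
    candidates = []
    for node, class_iri in subjects:
        for prop in _prop_map(schema, class_iri).values():
            kind = prop.multiplicity.ordered_kind
            if kind is OrderedKind.NONE:
                continue
            heads = list(out.objects(node, URIRef(prop.iri)))
            if heads:
                candidates.append((node, prop, heads[0], kind))
    node, prop, head, kind = _pick(rng, candidates)
    if kind is OrderedKind.ORDERED_LIST:
        # break the chain: drop the rdf:rest of the first cell
        rest = next(iter(out.objects(head, RDF.rest)))
        out.remove((head, RDF.rest, rest))
        detail = "removed an rdf:rest link from the collection"
    else:
        # shift rdf:_1 out of place so numbering no longer starts at 1
        first = URIRef(f"{RDF}_1")
        obj = next(iter(out.objects(head, first)))
        count = sum(1 for p, _ in out.predicate_objects(head)
                    if str(p).startswith(f"{RDF}_"))
        out.remove((head, first, obj))
        out.add((head, URIRef(f"{RDF}_{count + 1}"), obj))
        detail = "renumbered rdf:_1 so the container has a gap"
    return out, Mutation(ViolationKind.MALFORMED_LIST, seed,
                         (str(node), prop.iri), detail)


def _mut_non_schema_type(out, schema, rng, subjects, seed):
    node = URIRef(f"{schema.base_iri}data/extra{rng.randrange(10**6)}")
    bogus = URIRef(schema.base_iri + "NoSuchClass")
    out.add((node, RDF.type, bogus))
    return out, Mutation(ViolationKind.NON_SCHEMA_TYPE, seed,
                         (str(node), None),
                         "added a subject typed with a non-schema IRI")


_HANDLERS = {
    ViolationKind.MISSING_REQUIRED: _mut_missing_required,
    ViolationKind.CARDINALITY_EXCEEDED: _mut_cardinality,
    ViolationKind.UNKNOWN_PREDICATE: _mut_unknown_predicate,
    ViolationKind.WRONG_TARGET_TYPE: _mut_wrong_target_type,
    ViolationKind.UNTYPED_NODE: _mut_untyped_node,
    ViolationKind.VALUE_SET_VIOLATION: _mut_value_set,
    ViolationKind.MALFORMED_LIST: _mut_malformed_list,
    ViolationKind.NON_SCHEMA_TYPE: _mut_non_schema_type,
}


# ---------------------------------------------------------------------------
# random stores built through generated bindings


def random_store(schema: Schema, api, seed: int, n_instances: int):
    """Build a random instance store *through the generated bindings* —
    the correct-by-construction path — mirroring
    :func:`conforming_instances`."""
    rng = random.Random(seed)
    store = api.new_store()
    by_class: dict = {}
    pending: deque = deque()
    ext_counter = [0]

    def make(class_iri: str):
        cls = getattr(api, schema.classes[class_iri].name)
        instance = cls(store)
        by_class.setdefault(class_iri, []).append(instance)
        pending.append((instance, class_iri))
        return instance

    def value_for(target: TargetRef):
        if target.kind is TargetKind.PRIMITIVE:
            return {
                "string": lambda: "".join(rng.choice("abcdefgh")
                                          for _ in range(5)),
                "integer": lambda: rng.randrange(0, 10 ** 6),
                "double": lambda: round(rng.uniform(0, 1000), 3),
                "boolean": lambda: rng.random() < 0.5,
                "anyURI": lambda: f"http://external.example.org/u{rng.randrange(10**6)}",
            }[target.datatype]()
        if target.kind is TargetKind.VALUE_SET_REF:
            return rng.choice(sorted(schema.value_set_members(target.target_iri)))
        if target.kind is TargetKind.EXTERNAL_IRI:
            ext_counter[0] += 1
            return f"http://external.example.org/x{ext_counter[0]}"
        compatible = [target.target_iri] + sorted(
            schema.descendants(target.target_iri))
        existing = [i for c in compatible for i in by_class.get(c, ())]
        if existing and (len(store) > 50 or rng.random() < 0.7):
            return rng.choice(existing)
        return make(rng.choice(compatible))

    class_iris = sorted(schema.classes)
    for _ in range(n_instances):
        make(rng.choice(class_iris))
    while pending:
        instance, class_iri = pending.popleft()
        for prop in schema.effective_properties(class_iri):
            mult = prop.multiplicity
            if mult.min == 0 and rng.random() < 0.4:
                continue
            if mult.unbounded:
                for _ in range(rng.randint(max(mult.min, 1), 2)):
                    getattr(instance, f"add_{prop.name}")(value_for(prop.target))
            else:
                getattr(instance, f"set_{prop.name}")(value_for(prop.target))
    return store
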