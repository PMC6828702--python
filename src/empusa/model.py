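"""Language-neutral in-memory representation of a schema.

A :class:`Schema` holds OWL-style classes arranged in a single-parent
tree, each class owning an ordered list of typed, multiplicity-constrained
properties, plus controlled vocabularies ("value sets") modelled as a
subtree under an ``EnumeratedValue`` root.  Every other part of the
toolchain — reader, emitters, binding generator, validator, doc
generator — works from this one model.

Naming follows the ontology's human-readability principle: class names
are UpperCamelCase, property names lowerCamelCase; both are enforced at
construction time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, NamedTuple, Optional

from .errors import (
    CyclicHierarchy,
    DuplicateProperty,
    SchemaError,
    UnknownClass,
    UnknownValueSet,
    UnresolvedReference,
)

CLASS_NAME_RE = re.compile(r"^[A-Z][A-Za-z0-9]*$")
PROPERTY_NAME_RE = re.compile(r"^[a-z][A-Za-z0-9]*$")

#: IRI of the generic "any IRI" target used by the bare ``IRI`` dialect token.
ANY_IRI = "http://www.w3.org/2000/01/rdf-schema#Resource"

#: XSD datatypes accepted as primitive property targets.
PRIMITIVE_DATATYPES: Mapping[str, str] = {
    "string": "http://www.w3.org/2001/XMLSchema#string",
    "integer": "http://www.w3.org/2001/XMLSchema#integer",
    "double": "http://www.w3.org/2001/XMLSchema#double",
    "boolean": "http://www.w3.org/2001/XMLSchema#boolean",
    "anyURI": "http://www.w3.org/2001/XMLSchema#anyURI",
}


class _Unbounded:
    """Explicit upper-bound marker for ``0..N`` / ``1..N`` multiplicities."""

    _singleton: "_Unbounded | None" = None

    def __new__(cls) -> "_Unbounded":
        if cls._singleton is None:
            cls._singleton = super().__new__(cls)
        return cls._singleton

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "N"

    def __deepcopy__(self, memo) -> "_Unbounded":
        return self


UNBOUNDED = _Unbounded()


class OrderedKind(Enum):
    """How an unbounded property's values are organised in RDF."""

    NONE = "none"
    ORDERED_LIST = "ordered"    # '=' marker -> RDF collection
    NUMBERED_LIST = "numbered"  # '~' marker -> rdf:_1, rdf:_2, ... container


@dataclass(frozen=True)
class Multiplicity:
    """Occurrence constraint of a property: one of 0..1, 1..1, 0..N, 1..N.

    Only these four forms are legal; ``=``/``~`` list markers
    (``ordered_kind``) are meaningful only for the unbounded forms.
    """

    min: int
    max: object  # int 1 or UNBOUNDED
    ordered_kind: OrderedKind = OrderedKind.NONE

    def __post_init__(self) -> None:
        if self.min not in (0, 1):
            raise SchemaError(f"multiplicity min must be 0 or 1, got {self.min}")
        if self.max is not UNBOUNDED and self.max != 1:
            raise SchemaError(f"multiplicity max must be 1 or UNBOUNDED, got {self.max}")
        if not isinstance(self.ordered_kind, OrderedKind):
            raise SchemaError("ordered_kind must be an OrderedKind")
        if self.ordered_kind is not OrderedKind.NONE and self.max is not UNBOUNDED:
            raise SchemaError("list markers ('='/'~') require an unbounded multiplicity")

    @property
    def unbounded(self) -> bool:
        return self.max is UNBOUNDED

    @property
    def required(self) -> bool:
        return self.min == 1

    def token(self) -> str:
        """Serialize back to the dialect token, e.g. ``=0..N``."""
        marker = {OrderedKind.NONE: "", OrderedKind.ORDERED_LIST: "=",
                  OrderedKind.NUMBERED_LIST: "~"}[self.ordered_kind]
        return f"{marker}{self.min}..{'N' if self.unbounded else self.max}"


OPTIONAL = Multiplicity(0, 1)
REQUIRED = Multiplicity(1, 1)
ANY = Multiplicity(0, UNBOUNDED)
AT_LEAST_ONE = Multiplicity(1, UNBOUNDED)


class TargetKind(Enum):
    PRIMITIVE = "primitive"
    CLASS_REF = "class"
    VALUE_SET_REF = "value_set"
    EXTERNAL_IRI = "external"


@dataclass(frozen=True)
class TargetRef:
    """What a property points at: an XSD literal, a schema class, a value
    set, or an external (never dereferenced) IRI."""

    kind: TargetKind
    datatype: Optional[str] = None    # short name, e.g. "string"
    target_iri: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind is TargetKind.PRIMITIVE:
            if self.datatype not in PRIMITIVE_DATATYPES or self.target_iri is not None:
                raise SchemaError(f"bad primitive target: {self.datatype!r}")
        else:
            if self.datatype is not None or not self.target_iri:
                raise SchemaError(f"{self.kind.value} target needs exactly a target IRI")

    @classmethod
    def primitive(cls, datatype: str) -> "TargetRef":
        return cls(TargetKind.PRIMITIVE, datatype=datatype)

    @classmethod
    def class_ref(cls, iri: str) -> "TargetRef":
        return cls(TargetKind.CLASS_REF, target_iri=iri)

    @classmethod
    def value_set(cls, iri: str) -> "TargetRef":
        return cls(TargetKind.VALUE_SET_REF, target_iri=iri)

    @classmethod
    def external(cls, iri: str = ANY_IRI) -> "TargetRef":
        return cls(TargetKind.EXTERNAL_IRI, target_iri=iri)

    @property
    def datatype_iri(self) -> Optional[str]:
        if self.kind is TargetKind.PRIMITIVE:
            return PRIMITIVE_DATATYPES[self.datatype]
        return None


@dataclass(frozen=True)
class PropertyDef:
    """A single typed, multiplicity-constrained property of a class."""

    name: str
    iri: str
    target: TargetRef
    multiplicity: Multiplicity
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not PROPERTY_NAME_RE.match(self.name):
            raise SchemaError(
                f"property name {self.name!r} must be lowerCamelCase without whitespace"
            )
        if not self.iri:
            raise SchemaError(f"property {self.name!r} lacks an IRI")


@dataclass(frozen=True)
class AnnotationSet:
    """Human-facing annotations attached to a class or value set.

    ``definition`` is mandatory; the optional fields mirror the usage
    comment, editorial comment, GenBank/DDBJ feature-table label and
    skos:exactMatch cross-links to external ontologies.
    """

    definition: str
    usage_comment: Optional[str] = None
    editorial_comment: Optional[str] = None
    ddbj_label: Optional[str] = None
    exact_matches: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.definition or not self.definition.strip():
            raise SchemaError("annotation definition must be non-empty")
        object.__setattr__(self, "exact_matches", frozenset(self.exact_matches))
        for iri in self.exact_matches:
            if "://" not in iri and not iri.startswith("urn:"):
                raise SchemaError(f"exactMatch {iri!r} is not an absolute IRI")


@dataclass(frozen=True)
class ClassDef:
    """An OWL class with an ordered list of its *own* (non-inherited)
    properties and an optional single parent class."""

    iri: str
    name: str
    annotations: AnnotationSet
    parent: Optional[str] = None
    properties: tuple = ()

    def __post_init__(self) -> None:
        if not CLASS_NAME_RE.match(self.name):
            raise SchemaError(
                f"class name {self.name!r} must be UpperCamelCase without whitespace"
            )
        object.__setattr__(self, "properties", tuple(self.properties))
        seen_names: set = set()
        seen_iris: set = set()
        for prop in self.properties:
            if prop.name in seen_names:
                raise DuplicateProperty(f"{self.name}.{prop.name} defined twice")
            if prop.iri in seen_iris:
                raise DuplicateProperty(
                    f"property IRI <{prop.iri}> duplicated in class {self.name}"
                )
            seen_names.add(prop.name)
            seen_iris.add(prop.iri)


@dataclass(frozen=True)
class ValueSetDef:
    """A controlled vocabulary: a named set of member IRIs, possibly
    arranged as a tree (``members`` maps member IRI -> parent member IRI,
    or ``None`` for direct members of the set)."""

    iri: str
    name: str
    members: Mapping[str, Optional[str]]
    annotations: Optional[AnnotationSet] = None

    def __post_init__(self) -> None:
        if not CLASS_NAME_RE.match(self.name):
            raise SchemaError(f"value-set name {self.name!r} must be UpperCamelCase")
        members = dict(self.members)
        if not members:
            raise SchemaError(f"value set {self.name} has no members")
        for member, parent in members.items():
            if parent is not None and parent not in members:
                raise SchemaError(
                    f"value set {self.name}: member <{member}> has unknown parent <{parent}>"
                )
        object.__setattr__(self, "members", members)

    def member_iris(self) -> frozenset:
        """All members, including transitive sub-members (membership is
        closed under the member subtree)."""
        return frozenset(self.members)


class StatsRecord(NamedTuple):
    classes: int
    properties: int
    value_sets: int


@dataclass
class Schema:
    """A complete schema: class tree + value sets + namespace context.

    All referential invariants are checked eagerly at construction:
    single-parent acyclic hierarchy, resolvable class/value-set targets,
    disjoint class and value-set IRI spaces, and no property redefinition
    along an inheritance chain.
    """

    base_iri: str
    classes: dict = field(default_factory=dict)
    value_sets: dict = field(default_factory=dict)
    prefixes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction helpers ------------------------------------------------

    def validate(self) -> None:
        if not self.base_iri:
            raise SchemaError("schema needs a base IRI")
        overlap = set(self.classes) & set(self.value_sets)
        if overlap:
            raise SchemaError(f"IRIs used as both class and value set: {sorted(overlap)}")
        member_space = set()
        for vs in self.value_sets.values():
            member_space |= set(vs.members)
        clash = member_space & set(self.classes)
        if clash:
            raise SchemaError(f"IRIs used as both class and value-set member: {sorted(clash)}")

        for cls in self.classes.values():
            if cls.parent is not None and cls.parent not in self.classes:
                raise UnknownClass(
                    f"parent <{cls.parent}> of {cls.name} is not a class in the schema"
                )
        self._check_acyclic()

        for cls in self.classes.values():
            inherited = set()
            for anc in self.ancestors(cls.iri):
                inherited |= {p.name for p in self.classes[anc].properties}
            for prop in cls.properties:
                if prop.name in inherited:
                    raise DuplicateProperty(
                        f"{cls.name}.{prop.name} redefines an inherited property"
                    )
                self._check_target(cls, prop)

    def _check_acyclic(self) -> None:
        for start in self.classes:
            seen = {start}
            cur = self.classes[start].parent
            while cur is not None:
                if cur in seen:
                    raise CyclicHierarchy(f"subclass cycle through <{cur}>")
                seen.add(cur)
                cur = self.classes[cur].parent

    def _check_target(self, cls: ClassDef, prop: PropertyDef) -> None:
        t = prop.target
        if t.kind is TargetKind.CLASS_REF and t.target_iri not in self.classes:
            raise UnresolvedReference(cls.iri, prop.name, t.target_iri)
        if t.kind is TargetKind.VALUE_SET_REF and t.target_iri not in self.value_sets:
            raise UnresolvedReference(cls.iri, prop.name, t.target_iri)

    # -- hierarchy queries ---------------------------------------------------

    def ancestors(self, class_iri: str) -> Iterator[str]:
        """Parent chain of ``class_iri``, nearest first."""
        if class_iri not in self.classes:
            raise UnknownClass(f"<{class_iri}> is not a class in the schema")
        cur = self.classes[class_iri].parent
        while cur is not None:
            yield cur
            cur = self.classes[cur].parent

    def descendants(self, class_iri: str) -> frozenset:
        """All strict descendants of ``class_iri``."""
        if class_iri not in self.classes:
            raise UnknownClass(f"<{class_iri}> is not a class in the schema")
        out = set()
        frontier = [class_iri]
        children: dict = {}
        for cls in self.classes.values():
            if cls.parent is not None:
                children.setdefault(cls.parent, []).append(cls.iri)
        while frontier:
            for child in children.get(frontier.pop(), ()):
                if child not in out:
                    out.add(child)
                    frontier.append(child)
        return frozenset(out)

    def is_subclass_of(self, sub_iri: str, super_iri: str) -> bool:
        """Reflexive subclass test."""
        return sub_iri == super_iri or super_iri in set(self.ancestors(sub_iri))

    def roots(self) -> list:
        return [c.iri for c in self.classes.values() if c.parent is None]

    # -- the three shared queries -------------------------------------------

    def effective_properties(self, class_iri: str) -> list:
        """Own + inherited properties, ancestor-first (root's first)."""
        if class_iri not in self.classes:
            raise UnknownClass(f"<{class_iri}> is not a class in the schema")
        chain = list(self.ancestors(class_iri))[::-1] + [class_iri]
        out: list = []
        for iri in chain:
            out.extend(self.classes[iri].properties)
        return out

    def value_set_members(self, vs_iri: str) -> frozenset:
        if vs_iri not in self.value_sets:
            raise UnknownValueSet(f"<{vs_iri}> is not a value set in the schema")
        return self.value_sets[vs_iri].member_iris()

    def stats(self) -> StatsRecord:
        """Counts as printed in domain-overview tables: value-set member
        classes are tallied with their set, never with the classes."""
        n_props = sum(len(c.properties) for c in self.classes.values())
        return StatsRecord(len(self.classes), n_props, len(self.value_sets))

    # -- convenience ---------------------------------------------------------

    def iri(self, local_name: str) -> str:
        """Mint an IRI in the schema's own namespace."""
        return self.base_iri + local_name

    def class_by_name(self, name: str) -> ClassDef:
        for cls in self.classes.values():
            if cls.name == name:
                return cls
        raise UnknownClass(f"no class named {name!r}")


def schema_stats(schema: Schema) -> StatsRecord:
    """Module-level alias of :meth:`Schema.stats`."""
    return schema.stats()


def effective_properties(schema: Schema, class_iri: str) -> list:
    """Module-level alias of :meth:`Schema.effective_properties`."""
    return schema.effective_properties(class_iri)


def value_set_members(schema: Schema, vs_iri: str) -> frozenset:
    """Module-level alias of :meth:`Schema.value_set_members`."""
    return schema.value_set_members(vs_iri)
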