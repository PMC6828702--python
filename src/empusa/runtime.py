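"""Runtime support for generated data bindings.

Generated class modules subclass :class:`Instance` and call the generic
accessor helpers; all type and multiplicity checking lives here so the
generated code stays thin.  Values are checked twice: at set-time (fast
failure during data production) and again at export time (backstop), and
:func:`export_graph` refuses to serialize while any instance is missing
a required property or references an object outside the store.
"""

from __future__ import annotations

import enum
from typing import Optional

from .errors import (
    DanglingReference,
    MissingRequired,
    SchemaError,
    UnknownClass,
)
from .model import OrderedKind, PropertyDef, Schema, TargetKind

_XSD = "http://www.w3.org/2001/XMLSchema#"
_RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"


class InstanceStore:
    """Holds instances built through the generated API, in insertion order.

    IRIs are unique within a store: minted IRIs are collision-checked and
    explicit IRIs may not be registered twice (non-unique IRIs are a
    classic data-export error this API is meant to prevent).
    """

    def __init__(self, schema: Schema):
        self.schema = schema
        self._instances: dict = {}
        self._counters: dict = {}

    def mint_iri(self, class_name: str) -> str:
        while True:
            n = self._counters.get(class_name, 0) + 1
            self._counters[class_name] = n
            iri = f"{self.schema.base_iri}instance/{class_name}/{n}"
            if iri not in self._instances:
                return iri

    def register(self, instance: "Instance") -> None:
        if instance.iri in self._instances:
            raise SchemaError(f"IRI <{instance.iri}> already used in this store")
        self._instances[instance.iri] = instance

    def discard(self, iri: str) -> None:
        """Remove an instance (references to it become dangling)."""
        self._instances.pop(iri, None)

    def __contains__(self, iri: str) -> bool:
        return iri in self._instances

    def __iter__(self):
        return iter(self._instances.values())

    def __len__(self) -> int:
        return len(self._instances)

    def get(self, iri: str) -> Optional["Instance"]:
        return self._instances.get(iri)


class Instance:
    """Base class of every generated binding class.

    Subclasses set ``CLASS_IRI``; creating an instance records its
    ``rdf:type`` and registers it in the store immediately.
    """

    CLASS_IRI: str = ""

    def __init__(self, store: InstanceStore, iri: Optional[str] = None):
        if self.CLASS_IRI not in store.schema.classes:
            raise UnknownClass(
                f"{type(self).__name__} ({self.CLASS_IRI}) is not part of the "
                f"store's schema"
            )
        self._store = store
        self.iri = iri if iri is not None else store.mint_iri(type(self).__name__)
        self._values: dict = {}
        store.register(self)

    # -- property plumbing --------------------------------------------------

    def _prop(self, name: str) -> PropertyDef:
        for prop in self._store.schema.effective_properties(self.CLASS_IRI):
            if prop.name == name:
                return prop
        raise SchemaError(f"{type(self).__name__} has no property {name!r}")

    def _check(self, prop: PropertyDef, value):
        target = prop.target
        if target.kind is TargetKind.PRIMITIVE:
            expected = {"string": str, "integer": int, "double": (int, float),
                        "boolean": bool, "anyURI": str}[target.datatype]
            if target.datatype == "integer" and isinstance(value, bool):
                raise TypeError(f"{prop.name}: expected int, got bool")
            if not isinstance(value, expected):
                raise TypeError(
                    f"{prop.name}: expected xsd:{target.datatype}-compatible "
                    f"value, got {type(value).__name__}"
                )
            if target.datatype == "double":
                value = float(value)
            return value
        if target.kind is TargetKind.CLASS_REF:
            if not isinstance(value, Instance):
                raise TypeError(f"{prop.name}: expected a bound instance")
            if not self._store.schema.is_subclass_of(value.CLASS_IRI,
                                                     target.target_iri):
                raise TypeError(
                    f"{prop.name}: {type(value).__name__} is not a "
                    f"<{target.target_iri}>"
                )
            return value
        if target.kind is TargetKind.VALUE_SET_REF:
            iri = value.value if isinstance(value, enum.Enum) else value
            members = self._store.schema.value_set_members(target.target_iri)
            if iri not in members:
                raise ValueError(
                    f"{prop.name}: {iri!r} is not a member of "
                    f"<{target.target_iri}>"
                )
            return iri
        # EXTERNAL_IRI
        if not isinstance(value, str) or ("://" not in value
                                          and not value.startswith("urn:")):
            raise TypeError(f"{prop.name}: expected an absolute IRI string")
        return value

    def _set(self, name: str, value) -> None:
        prop = self._prop(name)
        if prop.multiplicity.unbounded:
            raise SchemaError(f"{name} is multi-valued; use add_{name}")
        self._values[name] = self._check(prop, value)

    def _get(self, name: str):
        prop = self._prop(name)
        if prop.multiplicity.unbounded:
            return tuple(self._values.get(name, ()))
        return self._values.get(name)

    def _add(self, name: str, value) -> None:
        prop = self._prop(name)
        if not prop.multiplicity.unbounded:
            raise SchemaError(f"{name} is single-valued; use set_{name}")
        self._values.setdefault(name, []).append(self._check(prop, value))

    def _remove(self, name: str, value) -> None:
        prop = self._prop(name)
        if not prop.multiplicity.unbounded:
            raise SchemaError(f"{name} is single-valued; use set_{name}")
        values = self._values.get(name, [])
        iri = value.value if isinstance(value, enum.Enum) else value
        try:
            values.remove(iri)
        except ValueError:
            raise ValueError(f"{name}: value not present") from None


# ---------------------------------------------------------------------------
# Turtle export


def _turtle_literal(prop: PropertyDef, value) -> str:
    datatype = prop.target.datatype
    if datatype == "string":
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') \
                          .replace("\n", "\\n") + '"'
    if datatype == "integer":
        return str(value)
    if datatype == "boolean":
        return "true" if value else "false"
    if datatype == "double":
        return f'"{value!r}"^^xsd:double'
    return f'"{value}"^^xsd:anyURI'


def _term(prop: PropertyDef, value) -> str:
    target = prop.target
    if target.kind is TargetKind.PRIMITIVE:
        return _turtle_literal(prop, value)
    if target.kind is TargetKind.CLASS_REF:
        return f"<{value.iri}>"
    return f"<{value}>"


def _collect_problems(store: InstanceStore):
    missing: list = []
    dangling: list = []
    for instance in store:
        for prop in store.schema.effective_properties(instance.CLASS_IRI):
            values = instance._values.get(prop.name)
            count = len(values) if isinstance(values, list) else \
                (0 if values is None else 1)
            if count < prop.multiplicity.min:
                missing.append((instance.iri, prop.name,
                                "required property is missing"))
            if prop.target.kind is TargetKind.CLASS_REF:
                refs = values if isinstance(values, list) else \
                    ([values] if values is not None else [])
                for ref in refs:
                    if store.get(ref.iri) is not ref:
                        dangling.append((instance.iri, prop.name,
                                         f"references <{ref.iri}> which is not "
                                         f"in the store"))
    return missing, dangling


def export_graph(store: InstanceStore, schema: Optional[Schema] = None) -> str:
    """Serialize the store to Turtle, refusing on constraint violations.

    Ordered-list properties become RDF collections ``( ... )``; numbered
    lists become ``rdf:_1``/``rdf:_2``/... containers so element numbering
    survives in the data.  Output is deterministic given insertion order.
    """
    schema = schema or store.schema
    missing, dangling = _collect_problems(store)
    if missing:
        raise MissingRequired(missing + dangling)
    if dangling:
        raise DanglingReference(
            "; ".join(f"{iri} {name}: {msg}" for iri, name, msg in dangling)
        )

    lines = [
        f"@prefix rdf: <{_RDF}> .",
        f"@prefix xsd: <{_XSD}> .",
        "",
    ]
    for instance in store:
        lines.append(f"<{instance.iri}> a <{instance.CLASS_IRI}> ;")
        body: list = []
        for prop in schema.effective_properties(instance.CLASS_IRI):
            values = instance._values.get(prop.name)
            if values is None or values == []:
                continue
            kind = prop.multiplicity.ordered_kind
            if kind is OrderedKind.ORDERED_LIST:
                items = " ".join(_term(prop, v) for v in values)
                body.append(f"    <{prop.iri}> ( {items} ) ;")
            elif kind is OrderedKind.NUMBERED_LIST:
                members = " ; ".join(
                    f"<{_RDF}_{i}> {_term(prop, v)}"
                    for i, v in enumerate(values, start=1)
                )
                body.append(f"    <{prop.iri}> [ {members} ] ;")
            elif isinstance(values, list):
                for v in values:
                    body.append(f"    <{prop.iri}> {_term(prop, v)} ;")
            else:
                body.append(f"    <{prop.iri}> {_term(prop, values)} ;")
        lines.extend(body)
        lines[-1] = lines[-1].removesuffix(" ;") + " ."
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"
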