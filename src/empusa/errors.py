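"""Exception hierarchy shared across the toolchain.

Structural problems in a schema definition raise :class:`SchemaError`
subclasses at construction/parse time; problems in *instance data* are
reported as :class:`~empusa.validate.Violation` records, never exceptions.
"""

from __future__ import annotations


class EmpusaError(Exception):
    """Base class for every error raised by this package."""


class SchemaError(EmpusaError):
    """A schema violates one of the model invariants."""


class UnknownClass(SchemaError):
    """A class IRI was looked up that is not part of the schema."""


class UnknownValueSet(SchemaError):
    """A value-set IRI was looked up that is not part of the schema."""


class UnresolvedReference(SchemaError):
    """A property targets a class/value set that does not exist.

    Carries the owning class IRI and property name so the offending
    definition line can be located.
    """

    def __init__(self, class_iri: str, property_name: str, target_iri: str):
        self.class_iri = class_iri
        self.property_name = property_name
        self.target_iri = target_iri
        super().__init__(
            f"property '{property_name}' of <{class_iri}> references "
            f"<{target_iri}> which is neither a class nor a value set"
        )


class CyclicHierarchy(SchemaError):
    """The rdfs:subClassOf graph contains a cycle."""


class DuplicateProperty(SchemaError):
    """The same property name occurs twice in one class (or clashes with
    an inherited property)."""


class DialectSyntaxError(SchemaError):
    """A malformed line inside a ``propertyDefinitions`` block.

    ``line`` is 1-based within the annotation value; ``class_iri`` names
    the class whose block failed to parse.
    """

    def __init__(self, message: str, *, class_iri: str | None = None,
                 line: int | None = None):
        self.class_iri = class_iri
        self.line = line
        where = ""
        if class_iri is not None:
            where += f" in <{class_iri}>"
        if line is not None:
            where += f" (line {line})"
        super().__init__(message + where)


class ExtensionError(SchemaError):
    """An extension subclass does not hang off the extension point."""


class InputError(EmpusaError):
    """An input file/graph could not be read or lacks required structure."""


class LocationSyntaxError(EmpusaError):
    """A GenBank-style location string could not be parsed."""


class ExportError(EmpusaError):
    """Instance export refused because the store violates the schema.

    ``problems`` is the full list of (instance IRI, property name, message)
    tuples; nothing is serialized while it is non-empty.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"{i} {p}: {m}" for i, p, m in self.problems)
        super().__init__(f"export refused, {len(self.problems)} problem(s): {lines}")


class MissingRequired(ExportError):
    """Required (min-cardinality 1) property absent on an instance."""


class DanglingReference(EmpusaError):
    """An object reference points outside the instance store."""


class GenerationError(EmpusaError):
    """The synthetic-instance generator cannot satisfy the schema."""


class NotApplicable(EmpusaError):
    """The requested mutation kind cannot be induced on this graph."""
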