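"""A small, self-contained ShExC parser and evaluator.

This module understands the ShExC subset the emitter produces — prefix
declarations, IRI-labelled shapes, ``CLOSED`` / ``EXTRA`` qualifiers,
triple constraints with ``? * +`` cardinalities, datatype constraints,
value sets, ``IRI`` node kinds, the ``.`` wildcard, shape references and
``OR`` disjunction — and evaluates RDF graphs against it.

It is deliberately independent of the rest of the toolchain: it never
sees a :class:`~empusa.model.Schema`, only the ShExC *text* and an
``rdflib`` graph, so it can serve as a second opinion on conformance
verdicts.  Shape references are evaluated co-inductively (a node is
assumed to satisfy a shape while that very test is in progress), the
standard greatest-fixpoint reading of recursive shapes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD


class ShexSyntaxError(Exception):
    """The ShExC text is outside the supported subset or malformed."""


class UnknownShape(Exception):
    """A shape reference points at a label that is not defined."""


# -- AST --------------------------------------------------------------------


@dataclass(frozen=True)
class Wildcard:
    pass


@dataclass(frozen=True)
class NodeKindIri:
    pass


@dataclass(frozen=True)
class DatatypeConstraint:
    datatype: str


@dataclass(frozen=True)
class ValueSetConstraint:
    values: frozenset


@dataclass(frozen=True)
class ShapeRef:
    label: str


@dataclass(frozen=True)
class Or:
    alternatives: tuple


@dataclass(frozen=True)
class TripleConstraint:
    predicate: str
    value: object
    min: int
    max: Optional[int]  # None = unbounded


@dataclass(frozen=True)
class Shape:
    constraints: tuple
    closed: bool = False
    extra: frozenset = frozenset()


# -- tokenizer / parser -----------------------------------------------------


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<comment>\#[^\n]*) |
        (?P<iri><[^<>\s]*>) |
        (?P<kw>PREFIX|EXTRA|CLOSED|OR|IRI\b) |
        (?P<at>@<[^<>\s]*>) |
        (?P<pname>[A-Za-z_][\w.-]*:[\w.-]*) |
        (?P<a>a\b) |
        (?P<punct>[\[\]{}();?*+.])
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list:
    tokens: list = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            if text[pos:].strip() == "":
                break
            raise ShexSyntaxError(f"cannot tokenize near: {text[pos:pos + 40]!r}")
        pos = match.end()
        kind = match.lastgroup
        if kind == "comment":
            continue
        tokens.append((kind, match.group(kind)))
    return tokens


class _Parser:
    def __init__(self, tokens: list):
        self.tokens = tokens
        self.pos = 0
        self.prefixes: dict = {}

    def peek(self) -> Optional[tuple]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple:
        tok = self.peek()
        if tok is None:
            raise ShexSyntaxError("unexpected end of input")
        self.pos += 1
        return tok

    def expect(self, kind: str, value: Optional[str] = None) -> str:
        tok = self.next()
        if tok[0] != kind or (value is not None and tok[1] != value):
            raise ShexSyntaxError(f"expected {value or kind}, got {tok[1]!r}")
        return tok[1]

    def resolve_pname(self, pname: str) -> str:
        prefix, local = pname.split(":", 1)
        if prefix not in self.prefixes:
            raise ShexSyntaxError(f"undeclared prefix {prefix!r}")
        return self.prefixes[prefix] + local

    # grammar ---------------------------------------------------------------

    def parse_schema(self) -> dict:
        shapes: dict = {}
        while self.peek() is not None:
            kind, value = self.peek()
            if kind == "kw" and value == "PREFIX":
                self.next()
                pname = self.expect("pname")
                iri = self.expect("iri")
                self.prefixes[pname.split(":", 1)[0]] = iri[1:-1]
            elif kind == "iri":
                label = self.next()[1][1:-1]
                shapes[label] = self.parse_shape_expr()
            else:
                raise ShexSyntaxError(f"unexpected top-level token {value!r}")
        return shapes

    def parse_shape_expr(self):
        alternatives = [self.parse_shape_atom()]
        while self.peek() is not None and self.peek() == ("kw", "OR"):
            self.next()
            alternatives.append(self.parse_shape_atom())
        if len(alternatives) == 1:
            return alternatives[0]
        return Or(tuple(alternatives))

    def parse_shape_atom(self):
        kind, value = self.peek()
        if kind == "punct" and value == "(":
            self.next()
            inner = self.parse_shape_expr()
            self.expect("punct", ")")
            return inner
        if kind == "punct" and value == "[":
            return self.parse_value_set()
        if kind == "punct" and value == ".":
            self.next()
            return Wildcard()
        if kind == "at":
            return ShapeRef(self.next()[1][2:-1])
        if kind == "kw" and value == "IRI":
            self.next()
            return NodeKindIri()
        if kind == "pname":
            return DatatypeConstraint(self.resolve_pname(self.next()[1]))
        if kind == "iri":
            return DatatypeConstraint(self.next()[1][1:-1])
        if (kind == "kw" and value in {"EXTRA", "CLOSED"}) or (
                kind == "punct" and value == "{"):
            return self.parse_shape_definition()
        raise ShexSyntaxError(f"unexpected token {value!r} in shape expression")

    def parse_value_set(self):
        self.expect("punct", "[")
        values: set = set()
        while self.peek() != ("punct", "]"):
            kind, value = self.next()
            if kind == "iri":
                values.add(value[1:-1])
            elif kind == "pname":
                values.add(self.resolve_pname(value))
            else:
                raise ShexSyntaxError(f"unexpected {value!r} inside value set")
        self.next()
        return ValueSetConstraint(frozenset(values))

    def parse_predicate(self) -> str:
        kind, value = self.next()
        if kind == "a":
            return str(RDF.type)
        if kind == "iri":
            return value[1:-1]
        if kind == "pname":
            return self.resolve_pname(value)
        raise ShexSyntaxError(f"bad predicate {value!r}")

    def parse_shape_definition(self) -> Shape:
        closed = False
        extra: set = set()
        while self.peek() is not None and self.peek()[0] == "kw" and \
                self.peek()[1] in {"EXTRA", "CLOSED"}:
            kw = self.next()[1]
            if kw == "CLOSED":
                closed = True
            else:
                extra.add(self.parse_predicate())
        self.expect("punct", "{")
        constraints: list = []
        while self.peek() != ("punct", "}"):
            constraints.append(self.parse_triple_constraint())
            if self.peek() == ("punct", ";"):
                self.next()
        self.next()
        return Shape(tuple(constraints), closed=closed, extra=frozenset(extra))

    def parse_triple_constraint(self) -> TripleConstraint:
        predicate = self.parse_predicate()
        value = self.parse_shape_expr()
        mn, mx = 1, 1
        if self.peek() is not None and self.peek()[0] == "punct" and \
                self.peek()[1] in {"?", "*", "+"}:
            card = self.next()[1]
            mn, mx = {"?": (0, 1), "*": (0, None), "+": (1, None)}[card]
        return TripleConstraint(predicate, value, mn, mx)


def parse_shex(text: str) -> dict:
    """Parse ShExC text into a ``{shape label: shape expression}`` map."""
    parser = _Parser(_tokenize(text))
    # The emitter indents constraint lines but tokenization is layout-free.
    return parser.parse_schema()


# -- evaluation -------------------------------------------------------------


class ShexEngine:
    """Evaluate nodes of an RDF graph against a parsed ShExC schema."""

    def __init__(self, shapes: dict):
        self.shapes = shapes
        # memoized (graph, node, shape-label) verdicts; without this,
        # cyclic reference structures make the coinductive search
        # exponential
        self._cache: dict = {}

    @classmethod
    def from_text(cls, text: str) -> "ShexEngine":
        return cls(parse_shex(text))

    def satisfies(self, graph: Graph, node, expr, _assume=None) -> bool:
        if _assume is None:
            _assume = set()
        if isinstance(expr, Wildcard):
            return True
        if isinstance(expr, Or):
            return any(self.satisfies(graph, node, alt, _assume)
                       for alt in expr.alternatives)
        if isinstance(expr, NodeKindIri):
            return isinstance(node, URIRef)
        if isinstance(expr, ValueSetConstraint):
            return isinstance(node, URIRef) and str(node) in expr.values
        if isinstance(expr, DatatypeConstraint):
            if not isinstance(node, Literal):
                return False
            datatype = str(node.datatype) if node.datatype is not None \
                else str(XSD.string)
            if node.language:
                return False
            return datatype == expr.datatype
        if isinstance(expr, ShapeRef):
            if expr.label not in self.shapes:
                raise UnknownShape(expr.label)
            key = (id(graph), node, expr.label)
            if key in self._cache:
                return self._cache[key]
            if (node, expr.label) in _assume:
                return True
            verdict = self.satisfies(graph, node, self.shapes[expr.label],
                                     _assume | {(node, expr.label)})
            # caching is sound under the greatest-fixpoint reading: the
            # assumptions of a successful derivation form a self-consistent
            # set, and assuming-true can only make a failed one more lenient
            self._cache[key] = verdict
            return verdict
        if isinstance(expr, Shape):
            return self._satisfies_shape(graph, node, expr, _assume)
        raise TypeError(f"unknown expression node {expr!r}")

    def _satisfies_shape(self, graph: Graph, node, shape: Shape, _assume) -> bool:
        if isinstance(node, Literal):
            return False
        outgoing: dict = {}
        for _, pred, obj in graph.triples((node, None, None)):
            outgoing.setdefault(str(pred), []).append(obj)
        constrained = {c.predicate for c in shape.constraints}
        if shape.closed:
            for pred in outgoing:
                if pred not in constrained:
                    return False
        for constraint in shape.constraints:
            objects = outgoing.get(constraint.predicate, [])
            matching = []
            for obj in objects:
                try:
                    ok = self.satisfies(graph, obj, constraint.value, _assume)
                except UnknownShape:
                    raise
                if ok:
                    matching.append(obj)
                elif constraint.predicate not in shape.extra:
                    # outside EXTRA, every occurrence must match
                    return False
            count = len(matching)
            if count < constraint.min:
                return False
            if constraint.max is not None and count > constraint.max:
                return False
        return True


def validate_with_engine(shex_text: str, graph: Graph, namespace: str):
    """Type-driven conformance check of a whole graph.

    Every subject carrying an ``rdf:type`` whose IRI has a shape is tested
    against that shape; a type inside ``namespace`` with *no* shape is a
    failure (the data claims a class the schema does not define).  Types
    outside the namespace (external ontologies) are ignored.

    Returns ``(conforms, failures)`` where failures is a list of
    ``(node, shape label or None, reason)`` tuples.
    """
    engine = ShexEngine.from_text(shex_text)
    failures: list = []
    for subject, type_iri in sorted(graph.subject_objects(RDF.type),
                                    key=lambda pair: (str(pair[0]), str(pair[1]))):
        label = str(type_iri)
        if label in engine.shapes:
            try:
                ok = engine.satisfies(graph, subject, ShapeRef(label))
            except UnknownShape as exc:
                ok = False
                failures.append((subject, label, f"unresolved shape reference {exc}"))
                continue
            if not ok:
                failures.append((subject, label, "does not satisfy shape"))
        elif label.startswith(namespace):
            failures.append((subject, None, f"no shape for in-namespace type {label}"))
    return (not failures, failures)
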