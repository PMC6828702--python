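"""GenBank-style location strings <-> location instances.

Coordinates follow the GenBank convention: 1-based, fully closed
intervals.  Supported syntax::

    100..200            region with exact begin/end
    <5..10   5..>10     fuzzy (before/after) bounds
    (102.110)..200      in-range bound inside a span
    one-of(3,5,9)..20   one-of bound inside a span
    467                 single base
    102.110             single base somewhere in a range
    102^103             in-between location (after base 102)
    complement(...)     reverse strand
    join(a,b,...)       ordered collection of regions
    order(a,b,...)      unordered collection of regions
    gap(43)             assembly gap of known length

Encoding goes through the generated data bindings, so every produced
location is schema-checked at construction time; decoding walks the
instances back to the canonical string, and ``decode(encode(s)) == s``
for canonical inputs.
"""

from __future__ import annotations

import re
import tempfile
from typing import Optional

from ..codegen import load_api
from ..errors import DanglingReference, LocationSyntaxError
from ..model import TargetKind
from ..runtime import Instance, InstanceStore
from ..validate import Violation, ViolationKind
from .demo import build_demo_schema
from .locations import GBOL

_API = None
_API_DIR = None


def get_api():
    """The (cached) generated binding module for the demo schema."""
    global _API, _API_DIR
    if _API is None:
        _API_DIR = tempfile.mkdtemp(prefix="empusa_gbol_api_")
        _API = load_api(build_demo_schema(), _API_DIR)
    return _API


def new_annotation_store() -> InstanceStore:
    return get_api().new_store()


# ---------------------------------------------------------------------------
# parsing


class _Parser:
    def __init__(self, text: str):
        self.text = text.replace(" ", "")
        self.pos = 0

    def error(self, message: str):
        raise LocationSyntaxError(
            f"{message} at offset {self.pos} in {self.text!r}")

    def peek(self, n: int = 1) -> str:
        return self.text[self.pos:self.pos + n]

    def eat(self, token: str) -> None:
        if not self.text.startswith(token, self.pos):
            self.error(f"expected {token!r}")
        self.pos += len(token)

    def integer(self) -> int:
        match = re.match(r"\d+", self.text[self.pos:])
        if not match:
            self.error("expected an integer")
        self.pos += match.end()
        return int(match.group())

    # location := complement | join | order | gap | span
    def location(self):
        for keyword in ("complement", "join", "order", "gap", "one-of"):
            if self.text.startswith(keyword + "(", self.pos):
                return getattr(self, "_" + keyword.replace("-", "_"))()
        return self.span()

    def _complement(self):
        self.eat("complement(")
        inner = self.location()
        self.eat(")")
        return ("complement", inner)

    def _members(self):
        members = [self.location()]
        while self.peek() == ",":
            self.eat(",")
            members.append(self.location())
        return members

    def _join(self):
        self.eat("join(")
        members = self._members()
        self.eat(")")
        return ("join", members)

    def _order(self):
        self.eat("order(")
        members = self._members()
        self.eat(")")
        return ("order", members)

    def _gap(self):
        self.eat("gap(")
        length = None
        if self.peek() != ")":
            length = self.integer()
        self.eat(")")
        return ("gap", length)

    def _one_of(self):
        point = self.point()
        return self._span_or_point(point)

    def span(self):
        return self._span_or_point(self.point())

    def _span_or_point(self, begin):
        if self.peek(2) == "..":
            self.eat("..")
            return ("span", begin, self.point())
        if self.peek() == "^":
            self.eat("^")
            after = self.integer()
            if begin[0] != "exact":
                self.error("in-between operands must be exact")
            if after != begin[1] + 1:
                self.error(
                    f"in-between location {begin[1]}^{after} must sit between "
                    f"adjacent bases on one sequence")
            return ("between", begin[1])
        return ("point", begin)

    # point := <n | >n | (a.b) | one-of(...) | n[.m]
    def point(self):
        ch = self.peek()
        if ch == "<":
            self.eat("<")
            return ("before", self.integer())
        if ch == ">":
            self.eat(">")
            return ("after", self.integer())
        if ch == "(":
            self.eat("(")
            low = self.integer()
            self.eat(".")
            high = self.integer()
            self.eat(")")
            return ("range", low, high, True)
        if self.text.startswith("one-of(", self.pos):
            self.eat("one-of(")
            values = [self.integer()]
            while self.peek() == ",":
                self.eat(",")
                values.append(self.integer())
            self.eat(")")
            return ("oneof", values)
        low = self.integer()
        if self.peek() == "." and self.peek(2) != "..":
            self.eat(".")
            return ("range", low, self.integer(), False)
        return ("exact", low)


def parse_location_string(text: str):
    """Parse into a small AST; raises :class:`LocationSyntaxError`."""
    if not text or not text.strip():
        raise LocationSyntaxError("empty location string")
    parser = _Parser(text.strip())
    node = parser.location()
    if parser.pos != len(parser.text):
        parser.error("trailing characters")
    return node


# ---------------------------------------------------------------------------
# encoding: AST -> instances


def _strandedness(store: InstanceStore, sequence_iri: str) -> str:
    sequence = store.get(sequence_iri)
    if sequence is None:
        raise DanglingReference(
            f"sequence <{sequence_iri}> is not registered in the store")
    strand_type = sequence.get_strandType()
    if strand_type is None:
        raise DanglingReference(
            f"sequence <{sequence_iri}> has no strandType set")
    return strand_type


def _make_position(api, store, point):
    kind = point[0]
    if kind == "exact":
        position = api.ExactPosition(store)
        position.set_position(point[1])
    elif kind == "before":
        position = api.BeforePosition(store)
        position.set_position(point[1])
    elif kind == "after":
        position = api.AfterPosition(store)
        position.set_position(point[1])
    elif kind == "range":
        position = api.InRangePosition(store)
        position.set_beginPosition(point[1])
        position.set_endPosition(point[2])
    else:  # oneof
        position = api.OneOfPosition(store)
        for value in point[1]:
            position.add_position(value)
    return position


def _build(api, store, node, sequence_iri: str, reverse: bool):
    forward_default = (
        _strandedness(store, sequence_iri) == GBOL + "DoubleStrandedDNA")
    kind = node[0]
    if kind == "complement":
        return _build(api, store, node[1], sequence_iri, not reverse)
    if kind in ("join", "order"):
        cls = (api.OrderedCollectionOfRegions if kind == "join"
               else api.UnorderedCollectionOfRegions)
        collection = cls(store)
        collection.set_reference(sequence_iri)
        for member in node[1]:
            region = _build(api, store, member, sequence_iri, reverse)
            if region.CLASS_IRI != GBOL + "Region":
                raise LocationSyntaxError(
                    f"{kind}() members must be simple regions")
            collection.add_memberRegions(region)
        return collection
    if kind == "gap":
        if node[1] is None:
            gap = api.Gap(store)
        else:
            gap = api.KnownLengthGap(store)
            gap.set_length(node[1])
        gap.set_reference(sequence_iri)
        return gap

    def strand_of():
        if reverse:
            return GBOL + "ReverseStrandPosition"
        if forward_default:
            return GBOL + "ForwardStrandPosition"
        return None

    if kind == "span":
        region = api.Region(store)
        region.set_reference(sequence_iri)
        region.set_begin(_make_position(api, store, node[1]))
        region.set_end(_make_position(api, store, node[2]))
        strand = strand_of()
        if strand is not None:
            region.set_strand(strand)
        return region
    if kind == "between":
        location = api.InBetweenLocation(store)
        location.set_reference(sequence_iri)
        location.set_after(_make_position(api, store, ("exact", node[1])))
        strand = strand_of()
        if strand is not None:
            location.set_strand(strand)
        return location
    # single point -> single base
    base = api.BaseLocation(store)
    base.set_reference(sequence_iri)
    base.set_at(_make_position(api, store, node[1]))
    strand = strand_of()
    if strand is not None:
        base.set_strand(strand)
    return base


def encode_location(location_string: str, sequence_iri: str,
                    store: InstanceStore) -> str:
    """Encode a GenBank location string as location instances in ``store``
    and return the IRI of the top-level Location instance.

    The referenced sequence must already be registered in the store with
    its strand type; regions on double-stranded DNA default to the
    forward strand, ``complement(...)`` selects the reverse strand, and
    no strand is recorded for single-stranded or protein sequences.
    """
    node = parse_location_string(location_string)
    api = get_api()
    return _build(api, store, node, sequence_iri, reverse=False).iri


# ---------------------------------------------------------------------------
# decoding: instances -> string


def _point_string(position: Instance, in_span: bool) -> str:
    cls = position.CLASS_IRI.rsplit("/", 1)[-1]
    if cls == "ExactPosition":
        return str(position.get_position())
    if cls == "BeforePosition":
        return f"<{position.get_position()}"
    if cls == "AfterPosition":
        return f">{position.get_position()}"
    if cls == "InRangePosition":
        body = f"{position.get_beginPosition()}.{position.get_endPosition()}"
        return f"({body})" if in_span else body
    if cls == "OneOfPosition":
        return "one-of(" + ",".join(str(v) for v in position.get_position()) + ")"
    raise LocationSyntaxError(f"cannot decode position class {cls}")


def decode_location(store: InstanceStore, location_iri: str) -> str:
    """Decode a Location instance back to its canonical GenBank string."""
    instance = store.get(location_iri)
    if instance is None:
        raise DanglingReference(f"<{location_iri}> is not in the store")
    cls = instance.CLASS_IRI.rsplit("/", 1)[-1]
    if cls in ("OrderedCollectionOfRegions", "UnorderedCollectionOfRegions"):
        members = [decode_location(store, m.iri)
                   for m in instance.get_memberRegions()]
        reverse = all(m.startswith("complement(") for m in members) and members
        if reverse:
            members = [m[len("complement("):-1] for m in members]
        keyword = "join" if cls.startswith("Ordered") else "order"
        body = f"{keyword}({','.join(members)})"
        return f"complement({body})" if reverse else body
    if cls == "KnownLengthGap":
        return f"gap({instance.get_length()})"
    if cls == "Gap":
        return "gap()"

    strand = getattr(instance, "get_strand", lambda: None)()
    reverse = strand == GBOL + "ReverseStrandPosition"
    if cls == "Region":
        body = (f"{_point_string(instance.get_begin(), True)}.."
                f"{_point_string(instance.get_end(), True)}")
    elif cls == "InBetweenLocation":
        after = instance.get_after().get_position()
        body = f"{after}^{after + 1}"
    elif cls == "BaseLocation":
        body = _point_string(instance.get_at(), False)
    else:
        raise LocationSyntaxError(f"cannot decode location class {cls}")
    return f"complement({body})" if reverse else body


# ---------------------------------------------------------------------------
# the strand rule


_UNSTRANDED = {GBOL + "SingleStrandedDNA", GBOL + "RNA", GBOL + "Protein"}


def strand_rule_check(store: InstanceStore, schema=None) -> list:
    """No strand may be specified for locations on single-stranded DNA,
    RNA or protein sequences; returns one violation per offender."""
    schema = schema or store.schema
    violations = []
    for instance in store:
        if instance.CLASS_IRI not in schema.classes:
            continue
        prop_names = {p.name for p in
                      schema.effective_properties(instance.CLASS_IRI)}
        if "strand" not in prop_names or "reference" not in prop_names:
            continue
        strand = instance.get_strand()
        if strand is None:
            continue
        reference = instance.get_reference()
        if reference is None:
            raise DanglingReference(
                f"stranded location <{instance.iri}> has no reference sequence")
        sequence = store.get(reference)
        if sequence is None:
            raise DanglingReference(
                f"location <{instance.iri}> references <{reference}> which is "
                f"not in the store")
        if sequence.get_strandType() in _UNSTRANDED:
            violations.append(Violation(
                ViolationKind.STRAND_RULE, instance.iri, GBOL + "strand",
                f"strand specified on a location whose sequence "
                f"<{reference}> is single-stranded or protein"))
    return violations
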