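"""The genomic-locations sub-ontology, built programmatically.

The location model is FALDO-inspired but redefined in its own namespace
with deliberate differences: strand is a property of Region, BaseLocation
and InBetweenLocation rather than a Position subclass; the ``reference``
(subject sequence) sits on Location, not on positions, so collections of
regions can span sequences; BaseLocation and InBetweenLocation are
first-class Location children; fuzzy positions hold plain integers
instead of nested position objects; there are no N-/C-terminal position
classes (protein indexes count from the N-terminal side) and no
``beginOf``/``endOf`` reflective properties.

The sub-ontology counts 16 classes, 17 properties and one value set
(StrandPosition: forward / reverse / both strands).
"""

from __future__ import annotations

from ..model import (
    ANY,
    AT_LEAST_ONE,
    AnnotationSet,
    ClassDef,
    Multiplicity,
    OPTIONAL,
    OrderedKind,
    PropertyDef,
    REQUIRED,
    Schema,
    TargetRef,
    UNBOUNDED,
    ValueSetDef,
)

GBOL = "http://gbol.life/0.1/"
FALDO = "http://biohackathon.org/resource/faldo#"

ORDERED_MANY = Multiplicity(1, UNBOUNDED, OrderedKind.ORDERED_LIST)


def _prop(name: str, target: TargetRef, mult, description: str) -> PropertyDef:
    return PropertyDef(name=name, iri=GBOL + name, target=target,
                       multiplicity=mult, description=description)


def _cls(name: str, definition: str, parent: str | None = None,
         properties=(), **ann) -> ClassDef:
    return ClassDef(
        iri=GBOL + name,
        name=name,
        parent=GBOL + parent if parent else None,
        properties=tuple(properties),
        annotations=AnnotationSet(definition=definition, **ann),
    )


def build_locations_schema() -> Schema:
    """The bundled genomic-locations fixture schema (16 classes / 17
    properties / 1 value set)."""
    position_ref = TargetRef.class_ref(GBOL + "Position")
    strand_ref = TargetRef.value_set(GBOL + "StrandPosition")
    integer = TargetRef.primitive("integer")

    strand = _prop("strand", strand_ref, OPTIONAL,
                   "strand of the interval; omit for single-stranded or "
                   "protein sequences")

    classes = [
        _cls("Location",
             "An interval or point on one or more sequences; every concrete "
             "location kind is a subclass.",
             properties=[
                 _prop("reference", TargetRef.external(), REQUIRED,
                       "the sequence this location is defined on; a location "
                       "spanning sequences is expressed through a collection "
                       "whose member regions each carry their own reference"),
             ]),
        _cls("Region",
             "A contiguous stretch with a begin and an end position.",
             parent="Location",
             exact_matches={FALDO + "Region"},
             properties=[
                 _prop("begin", position_ref, REQUIRED,
                       "position of the first base of the region"),
                 _prop("end", position_ref, REQUIRED,
                       "position of the last base of the region"),
                 strand,
             ]),
        _cls("BaseLocation",
             "A single base at a given position.",
             parent="Location",
             properties=[
                 _prop("at", position_ref, REQUIRED,
                       "position object of the single base; may be fuzzy"),
                 strand,
             ]),
        _cls("InBetweenLocation",
             "A location between two adjacent bases, identified by the base "
             "after which it lies (GenBank a^b).",
             parent="Location",
             properties=[
                 _prop("after", position_ref, REQUIRED,
                       "position of the base after which the in-between "
                       "location lies"),
                 strand,
             ]),
        _cls("CollectionOfRegions",
             "A location composed of several regions, possibly on different "
             "sequences.",
             parent="Location"),
        _cls("OrderedCollectionOfRegions",
             "A collection of regions whose member order is meaningful "
             "(GenBank join).",
             parent="CollectionOfRegions",
             properties=[
                 _prop("memberRegions", TargetRef.class_ref(GBOL + "Region"),
                       ORDERED_MANY, "member regions, in reading order"),
             ]),
        _cls("UnorderedCollectionOfRegions",
             "A collection of regions without a meaningful member order "
             "(GenBank order).",
             parent="CollectionOfRegions",
             properties=[
                 _prop("memberRegions", TargetRef.class_ref(GBOL + "Region"),
                       AT_LEAST_ONE, "member regions, unordered"),
             ]),
        _cls("Gap",
             "An assembly gap of unknown length between joined regions "
             "(GenBank gap()).",
             parent="Location",
             ddbj_label="gap"),
        _cls("KnownLengthGap",
             "An assembly gap whose length in bases is known "
             "(GenBank gap(N)).",
             parent="Gap",
             properties=[
                 _prop("length", integer, REQUIRED, "gap length in bases"),
             ]),
        _cls("Position",
             "A single coordinate on a sequence; 1-based.",
             exact_matches={FALDO + "Position"}),
        _cls("ExactPosition",
             "A coordinate known exactly.",
             parent="Position",
             exact_matches={FALDO + "ExactPosition"},
             properties=[
                 _prop("position", integer, REQUIRED, "the 1-based coordinate"),
             ]),
        _cls("FuzzyPosition",
             "A coordinate that is not exactly known; subclasses hold plain "
             "integers rather than nested position objects.",
             parent="Position",
             exact_matches={FALDO + "FuzzyPosition"}),
        _cls("BeforePosition",
             "A coordinate known to lie before (at most) the given value "
             "(GenBank <n).",
             parent="FuzzyPosition",
             exact_matches={FALDO + "BeforePosition"},
             properties=[
                 _prop("position", integer, REQUIRED,
                       "upper bound of the coordinate"),
             ]),
        _cls("AfterPosition",
             "A coordinate known to lie after (at least) the given value "
             "(GenBank >n).",
             parent="FuzzyPosition",
             exact_matches={FALDO + "AfterPosition"},
             properties=[
                 _prop("position", integer, REQUIRED,
                       "lower bound of the coordinate"),
             ]),
        _cls("InRangePosition",
             "A coordinate somewhere between two bounds (GenBank a.b).",
             parent="FuzzyPosition",
             exact_matches={FALDO + "InRangePosition"},
             properties=[
                 _prop("beginPosition", integer, REQUIRED,
                       "lower bound of the coordinate"),
                 _prop("endPosition", integer, REQUIRED,
                       "upper bound of the coordinate"),
             ]),
        _cls("OneOfPosition",
             "A coordinate that is one of an explicit set of values "
             "(GenBank one-of).",
             parent="FuzzyPosition",
             exact_matches={FALDO + "OneOfPosition"},
             properties=[
                 _prop("position", integer, AT_LEAST_ONE,
                       "the candidate coordinates"),
             ]),
    ]

    strand_set = ValueSetDef(
        iri=GBOL + "StrandPosition",
        name="StrandPosition",
        members={
            GBOL + "ForwardStrandPosition": None,
            GBOL + "ReverseStrandPosition": None,
            GBOL + "BothStrandsPosition": None,
        },
        annotations=AnnotationSet(
            definition="Strand of an interval: forward, reverse or both; "
                       "not a Position subclass.",
            exact_matches={FALDO + "StrandedPosition"},
        ),
    )

    return Schema(
        base_iri=GBOL,
        classes={c.iri: c for c in classes},
        value_sets={strand_set.iri: strand_set},
        prefixes={"gbol": GBOL, "faldo": FALDO},
    )


#: Enumerated reconstruction of the 16-class membership, kept alongside the
#: fixture for auditability (the figure the counts come from names 12
#: classes explicitly; the remaining 4 are structural reconstructions).
LOCATIONS_MANIFEST = {
    "named_in_figure": [
        "Location", "Region", "CollectionOfRegions", "BaseLocation",
        "InBetweenLocation", "Position", "ExactPosition", "FuzzyPosition",
        "BeforePosition", "AfterPosition", "InRangePosition", "OneOfPosition",
    ],
    "reconstructed": {
        "OrderedCollectionOfRegions": "ordered variant of CollectionOfRegions",
        "UnorderedCollectionOfRegions": "unordered variant of CollectionOfRegions",
        "Gap": "unknown-length assembly gap (GenBank gap() operator)",
        "KnownLengthGap": "known-length assembly gap (GenBank gap(N) operator)",
    },
    "value_set": {
        "StrandPosition": ["ForwardStrandPosition", "ReverseStrandPosition",
                           "BothStrandsPosition"],
    },
    "counts": {"classes": 16, "properties": 17, "value_sets": 1},
}
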