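import pytest

from empusa.codegen import load_api
from empusa.gbol import build_demo_schema, build_locations_schema, get_api
from empusa.model import (
    ANY,
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

BASE = "http://example.org/zoo/"


def _ann(definition):
    return AnnotationSet(definition=definition)


def build_zoo_schema() -> Schema:
    """Small hand-written schema touching every target kind, all four
    multiplicities and both list encodings."""
    animal = ClassDef(
        iri=BASE + "Animal", name="Animal", annotations=_ann("An animal."),
        properties=(
            PropertyDef("name", BASE + "name", TargetRef.primitive("string"),
                        REQUIRED, "the name"),
            PropertyDef("age", BASE + "age", TargetRef.primitive("integer"),
                        OPTIONAL),
        ))
    dog = ClassDef(
        iri=BASE + "Dog", name="Dog", annotations=_ann("A dog."),
        parent=BASE + "Animal",
        properties=(
            PropertyDef("friend", BASE + "friend",
                        TargetRef.class_ref(BASE + "Animal"), ANY),
            PropertyDef("coat", BASE + "coat",
                        TargetRef.value_set(BASE + "CoatColour"), OPTIONAL),
            PropertyDef("toys", BASE + "toys", TargetRef.primitive("string"),
                        Multiplicity(0, UNBOUNDED, OrderedKind.ORDERED_LIST)),
            PropertyDef("ranks", BASE + "ranks",
                        TargetRef.primitive("integer"),
                        Multiplicity(1, UNBOUNDED, OrderedKind.NUMBERED_LIST)),
            PropertyDef("homepage", BASE + "homepage", TargetRef.external(),
                        OPTIONAL),
        ))
    coat = ValueSetDef(
        iri=BASE + "CoatColour", name="CoatColour",
        members={BASE + "Black": None, BASE + "Brown": None,
                 BASE + "DarkBrown": BASE + "Brown"},
        annotations=_ann("Coat colours."))
    return Schema(base_iri=BASE,
                  classes={c.iri: c for c in (animal, dog)},
                  value_sets={coat.iri: coat})


@pytest.fixture(scope="session")
def zoo_schema():
    return build_zoo_schema()


@pytest.fixture(scope="session")
def zoo_api(tmp_path_factory):
    return load_api(build_zoo_schema(), tmp_path_factory.mktemp("zoo_api"))


@pytest.fixture(scope="session")
def locations_schema():
    return build_locations_schema()


@pytest.fixture(scope="session")
def demo_schema():
    return build_demo_schema()


@pytest.fixture(scope="session")
def gbol_api():
    return get_api()
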