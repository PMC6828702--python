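"""Schema model invariants: naming rules, multiplicity forms, hierarchy
checks, and the three shared queries (stats, flattening, members)."""

import pytest

from empusa.errors import (
    CyclicHierarchy,
    DuplicateProperty,
    SchemaError,
    UnknownClass,
    UnknownValueSet,
    UnresolvedReference,
)
from empusa.model import (
    AnnotationSet,
    ClassDef,
    Multiplicity,
    OrderedKind,
    PropertyDef,
    REQUIRED,
    Schema,
    TargetRef,
    UNBOUNDED,
    ValueSetDef,
    schema_stats,
)
from empusa.testkit import random_schema

BASE = "http://example.org/m/"


def _ann(text="A class."):
    return AnnotationSet(definition=text)


def _cls(name, parent=None, props=()):
    return ClassDef(iri=BASE + name, name=name, annotations=_ann(),
                    parent=BASE + parent if parent else None,
                    properties=tuple(props))


def _prop(name, mult=REQUIRED, target=None):
    return PropertyDef(name=name, iri=BASE + name,
                       target=target or TargetRef.primitive("string"),
                       multiplicity=mult)


class TestMultiplicity:
    @pytest.mark.parametrize("mn,mx", [(0, 1), (1, 1)])
    def test_bounded_forms(self, mn, mx):
        assert not Multiplicity(mn, mx).unbounded

    @pytest.mark.parametrize("mn", [0, 1])
    def test_unbounded_forms(self, mn):
        assert Multiplicity(mn, UNBOUNDED).unbounded

    @pytest.mark.parametrize("mn,mx", [(2, 1), (0, 2), (-1, 1), (0, 0)])
    def test_only_the_four_paper_forms_are_legal(self, mn, mx):
        with pytest.raises(SchemaError):
            Multiplicity(mn, mx)

    def test_list_marker_requires_unbounded_max(self):
        with pytest.raises(SchemaError):
            Multiplicity(1, 1, OrderedKind.ORDERED_LIST)
        # fine on unbounded
        Multiplicity(0, UNBOUNDED, OrderedKind.NUMBERED_LIST)

    def test_token_round_trips_through_reader(self):
        from empusa.reader import parse_multiplicity
        for mult in (Multiplicity(0, 1), Multiplicity(1, 1),
                     Multiplicity(0, UNBOUNDED),
                     Multiplicity(1, UNBOUNDED, OrderedKind.ORDERED_LIST),
                     Multiplicity(1, UNBOUNDED, OrderedKind.NUMBERED_LIST)):
            assert parse_multiplicity(mult.token()) == mult


class TestNaming:
    @pytest.mark.parametrize("bad", ["exact position", "exactPosition",
                                     "3Prime", ""])
    def test_class_names_must_be_upper_camel(self, bad):
        with pytest.raises(SchemaError):
            ClassDef(iri=BASE + "X", name=bad, annotations=_ann())

    @pytest.mark.parametrize("bad", ["Regulatory", "regulatory class", "_x", ""])
    def test_property_names_must_be_lower_camel(self, bad):
        with pytest.raises(SchemaError):
            _prop(bad)

    def test_target_ref_is_exclusive(self):
        with pytest.raises(SchemaError):
            TargetRef.primitive("complex")
        with pytest.raises(SchemaError):
            TargetRef(kind=TargetRef.primitive("string").kind,
                      datatype="string", target_iri="http://x/")

    def test_annotation_definition_required(self):
        with pytest.raises(SchemaError):
            AnnotationSet(definition="  ")


class TestHierarchy:
    def test_cycle_rejected(self):
        a = _cls("A", parent="B")
        b = _cls("B", parent="A")
        with pytest.raises(CyclicHierarchy):
            Schema(base_iri=BASE, classes={a.iri: a, b.iri: b})

    def test_missing_parent_rejected(self):
        a = _cls("A", parent="Nowhere")
        with pytest.raises(UnknownClass):
            Schema(base_iri=BASE, classes={a.iri: a})

    def test_property_redefinition_in_subclass_rejected(self):
        a = _cls("A", props=[_prop("size")])
        b = _cls("B", parent="A", props=[_prop("size")])
        with pytest.raises(DuplicateProperty):
            Schema(base_iri=BASE, classes={a.iri: a, b.iri: b})

    def test_duplicate_property_within_class_rejected(self):
        with pytest.raises(DuplicateProperty):
            _cls("A", props=[_prop("size"), _prop("size")])

    def test_dangling_class_ref_rejected(self):
        a = _cls("A", props=[_prop("next", target=TargetRef.class_ref(
            BASE + "Protien"))])
        with pytest.raises(UnresolvedReference) as err:
            Schema(base_iri=BASE, classes={a.iri: a})
        assert "Protien" in str(err.value)


class TestQueries:
    def test_stats_of_empty_schema(self):
        assert schema_stats(Schema(base_iri=BASE)) == (0, 0, 0)

    def test_stats_counts_owned_properties_and_sets(self):
        vs = ValueSetDef(iri=BASE + "S", name="S",
                         members={BASE + "M1": None, BASE + "M2": None,
                                  BASE + "M3": None})
        a = _cls("A", props=[_prop("one"), _prop("two")])
        schema = Schema(base_iri=BASE, classes={a.iri: a},
                        value_sets={vs.iri: vs})
        # value-set member classes are tallied with the set, not the classes
        assert schema.stats() == (1, 2, 1)

    def test_stats_additive_over_disjoint_unions(self):
        for seed_a, seed_b in [(1, 2), (5, 9)]:
            a = random_schema(seed_a, n_classes=6)
            b = random_schema(seed_b, n_classes=4)
            union = Schema(
                base_iri=a.base_iri,
                classes={**a.classes, **b.classes},
                value_sets={**a.value_sets, **b.value_sets})
            expected = tuple(x + y for x, y in zip(a.stats(), b.stats()))
            assert tuple(union.stats()) == expected

    def test_effective_properties_of_root(self):
        a = _cls("A", props=[_prop("one"), _prop("two")])
        schema = Schema(base_iri=BASE, classes={a.iri: a})
        assert [p.name for p in schema.effective_properties(a.iri)] == \
            ["one", "two"]

    def test_effective_properties_ancestor_first_chain(self):
        a = _cls("A", props=[_prop("pa")])
        b = _cls("B", parent="A", props=[_prop("pb")])
        c = _cls("C", parent="B", props=[_prop("pc")])
        schema = Schema(base_iri=BASE,
                        classes={x.iri: x for x in (a, b, c)})
        assert [p.name for p in schema.effective_properties(c.iri)] == \
            ["pa", "pb", "pc"]

    def test_effective_properties_unknown_class(self):
        with pytest.raises(UnknownClass):
            Schema(base_iri=BASE).effective_properties(BASE + "X")

    @pytest.mark.parametrize("seed", range(8))
    def test_effective_properties_matches_brute_force(self, seed):
        """Flattening agrees with a naive parent-chain walk, and is
        idempotent, on random schemas."""
        schema = random_schema(seed, n_classes=20, n_value_sets=2)
        for iri, cls in schema.classes.items():
            chain = []
            cursor = cls
            while cursor is not None:
                chain.append(cursor)
                cursor = schema.classes.get(cursor.parent)
            expected = [p for c in reversed(chain) for p in c.properties]
            assert schema.effective_properties(iri) == expected
            assert schema.effective_properties(iri) == \
                schema.effective_properties(iri)

    def test_value_set_members_transitive(self):
        vs = ValueSetDef(iri=BASE + "S", name="S",
                         members={BASE + "A": None,
                                  BASE + "A1": BASE + "A",
                                  BASE + "A2": BASE + "A"})
        schema = Schema(base_iri=BASE, value_sets={vs.iri: vs})
        assert schema.value_set_members(vs.iri) == \
            {BASE + "A", BASE + "A1", BASE + "A2"}

    def test_value_set_members_unknown_set(self):
        with pytest.raises(UnknownValueSet):
            Schema(base_iri=BASE).value_set_members(BASE + "S")

    def test_empty_value_set_rejected(self):
        with pytest.raises(SchemaError):
            ValueSetDef(iri=BASE + "S", name="S", members={})

    def test_class_and_value_set_iri_spaces_disjoint(self):
        vs = ValueSetDef(iri=BASE + "A", name="A", members={BASE + "M": None})
        a = _cls("A")
        with pytest.raises(SchemaError):
            Schema(base_iri=BASE, classes={a.iri: a}, value_sets={vs.iri: vs})

    def test_subclass_queries(self, zoo_schema):
        dog = BASE.replace("m/", "") and "http://example.org/zoo/Dog"
        animal = "http://example.org/zoo/Animal"
        assert zoo_schema.is_subclass_of(dog, animal)
        assert not zoo_schema.is_subclass_of(animal, dog)
        assert zoo_schema.descendants(animal) == {dog}
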