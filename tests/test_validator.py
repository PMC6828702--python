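"""Closed-world validation: one focused case per violation kind, plus
subclass substitutability and report mechanics."""

import pytest
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD

from empusa.errors import InputError
from empusa.validate import (
    ViolationKind,
    check_instance,
    validate_graph,
)

ZOO = "http://example.org/zoo/"
DATA = "http://example.org/data/"


def _uri(local, ns=ZOO):
    return URIRef(ns + local)


@pytest.fixture
def conforming_zoo_graph():
    graph = Graph()
    rex, fido = _uri("rex", DATA), _uri("fido", DATA)
    graph.add((rex, RDF.type, _uri("Animal")))
    graph.add((rex, _uri("name"), Literal("rex")))
    graph.add((fido, RDF.type, _uri("Dog")))
    graph.add((fido, _uri("name"), Literal("fido")))
    graph.add((fido, _uri("age"), Literal(3)))
    graph.add((fido, _uri("friend"), rex))
    graph.add((fido, _uri("coat"), _uri("DarkBrown")))
    cell = BNode("c1")
    graph.add((fido, _uri("toys"), cell))
    graph.add((cell, RDF.first, Literal("ball")))
    graph.add((cell, RDF.rest, RDF.nil))
    box = BNode("n1")
    graph.add((fido, _uri("ranks"), box))
    graph.add((box, URIRef(str(RDF) + "_1"), Literal(7)))
    return graph


def test_conforming_graph_yields_no_violations(conforming_zoo_graph,
                                               zoo_schema):
    report = validate_graph(conforming_zoo_graph, zoo_schema)
    assert report.conforms and report.checked_instances == 2


def test_empty_graph_conforms(zoo_schema):
    report = validate_graph(Graph(), zoo_schema)
    assert report.conforms and report.checked_instances == 0


class TestEachKind:
    def _kinds(self, graph, schema):
        return validate_graph(graph, schema).kinds()

    def test_missing_required(self, conforming_zoo_graph, zoo_schema):
        conforming_zoo_graph.remove((_uri("fido", DATA), _uri("name"), None))
        assert self._kinds(conforming_zoo_graph, zoo_schema) == \
            {ViolationKind.MISSING_REQUIRED}

    def test_cardinality_exceeded_on_optional_single(self, conforming_zoo_graph,
                                                     zoo_schema):
        conforming_zoo_graph.add((_uri("fido", DATA), _uri("age"), Literal(4)))
        assert self._kinds(conforming_zoo_graph, zoo_schema) == \
            {ViolationKind.CARDINALITY_EXCEEDED}

    def test_predicate_typo_is_unknown_predicate(self, conforming_zoo_graph,
                                                 zoo_schema):
        fido = _uri("fido", DATA)
        conforming_zoo_graph.remove((fido, _uri("age"), None))
        conforming_zoo_graph.add((fido, _uri("agee"), Literal(3)))
        assert self._kinds(conforming_zoo_graph, zoo_schema) == \
            {ViolationKind.UNKNOWN_PREDICATE}

    def test_wrong_literal_datatype(self, conforming_zoo_graph, zoo_schema):
        fido = _uri("fido", DATA)
        conforming_zoo_graph.remove((fido, _uri("age"), None))
        conforming_zoo_graph.add((fido, _uri("age"),
                                  Literal("three", datatype=XSD.string)))
        assert self._kinds(conforming_zoo_graph, zoo_schema) == \
            {ViolationKind.WRONG_TARGET_TYPE}

    def test_sibling_typed_object_is_wrong_target_type(self, zoo_schema):
        graph = Graph()
        fido, thing = _uri("fido", DATA), _uri("thing", DATA)
        graph.add((fido, RDF.type, _uri("Dog")))
        graph.add((fido, _uri("name"), Literal("fido")))
        box = BNode()
        graph.add((fido, _uri("ranks"), box))
        graph.add((box, URIRef(str(RDF) + "_1"), Literal(1)))
        graph.add((fido, _uri("friend"), thing))
        graph.add((thing, RDF.type, _uri("CoatColour")))  # not an Animal
        kinds = validate_graph(graph, zoo_schema).kinds()
        assert ViolationKind.WRONG_TARGET_TYPE in kinds

    def test_untyped_referenced_node(self, conforming_zoo_graph, zoo_schema):
        conforming_zoo_graph.remove((_uri("rex", DATA), RDF.type, None))
        assert self._kinds(conforming_zoo_graph, zoo_schema) == \
            {ViolationKind.UNTYPED_NODE}

    def test_value_set_violation(self, conforming_zoo_graph, zoo_schema):
        fido = _uri("fido", DATA)
        conforming_zoo_graph.remove((fido, _uri("coat"), None))
        conforming_zoo_graph.add((fido, _uri("coat"), _uri("Purple")))
        assert self._kinds(conforming_zoo_graph, zoo_schema) == \
            {ViolationKind.VALUE_SET_VIOLATION}

    def test_broken_collection_is_malformed_list(self, conforming_zoo_graph,
                                                 zoo_schema):
        conforming_zoo_graph.remove((BNode("c1"), RDF.rest, RDF.nil))
        assert self._kinds(conforming_zoo_graph, zoo_schema) == \
            {ViolationKind.MALFORMED_LIST}

    def test_gapped_container_is_malformed_list(self, conforming_zoo_graph,
                                                zoo_schema):
        box = BNode("n1")
        conforming_zoo_graph.remove((box, URIRef(str(RDF) + "_1"), None))
        conforming_zoo_graph.add((box, URIRef(str(RDF) + "_2"), Literal(7)))
        assert self._kinds(conforming_zoo_graph, zoo_schema) == \
            {ViolationKind.MALFORMED_LIST}

    def test_non_schema_type_inside_namespace(self, conforming_zoo_graph,
                                              zoo_schema):
        conforming_zoo_graph.add((_uri("x", DATA), RDF.type, _uri("Unicorn")))
        assert self._kinds(conforming_zoo_graph, zoo_schema) == \
            {ViolationKind.NON_SCHEMA_TYPE}

    def test_foreign_namespace_types_are_ignored(self, conforming_zoo_graph,
                                                 zoo_schema):
        conforming_zoo_graph.add((_uri("x", DATA), RDF.type,
                                  URIRef("http://xmlns.com/foaf/0.1/Person")))
        assert validate_graph(conforming_zoo_graph, zoo_schema).conforms


class TestSemantics:
    def test_subclass_substitutability(self, zoo_schema):
        """A Dog is acceptable wherever an Animal is required."""
        graph = Graph()
        fido, spot = _uri("fido", DATA), _uri("spot", DATA)
        for dog in (fido, spot):
            graph.add((dog, RDF.type, _uri("Dog")))
            graph.add((dog, _uri("name"), Literal("a")))
            box = BNode(f"r{dog}")
            graph.add((dog, _uri("ranks"), box))
            graph.add((box, URIRef(str(RDF) + "_1"), Literal(1)))
        graph.add((fido, _uri("friend"), spot))  # friend expects Animal
        assert validate_graph(graph, zoo_schema).conforms

    def test_untyped_literal_for_integer_is_warning_not_violation(self,
                                                                  zoo_schema):
        graph = Graph()
        rex = _uri("rex", DATA)
        graph.add((rex, RDF.type, _uri("Animal")))
        graph.add((rex, _uri("name"), Literal("rex")))
        graph.add((rex, _uri("age"), Literal("3", datatype=None)))
        report = validate_graph(graph, zoo_schema)
        assert report.conforms and report.warnings

    def test_check_instance_matches_validate_graph(self, conforming_zoo_graph,
                                                   zoo_schema):
        fido = _uri("fido", DATA)
        conforming_zoo_graph.remove((fido, _uri("name"), None))
        whole = validate_graph(conforming_zoo_graph, zoo_schema)
        single = check_instance(fido, ZOO + "Dog", conforming_zoo_graph,
                                zoo_schema)
        assert [v.key() for v in whole.violations] == \
            [v.key() for v in single]

    def test_check_instance_with_unknown_class_reports_not_raises(self,
                                                                  zoo_schema):
        graph = Graph()
        node = _uri("x", DATA)
        graph.add((node, RDF.type, _uri("Unicorn")))
        violations = check_instance(node, ZOO + "Unicorn", graph, zoo_schema)
        assert [v.kind for v in violations] == [ViolationKind.NON_SCHEMA_TYPE]

    def test_violations_deduplicated_by_kind_subject_predicate(self,
                                                               zoo_schema):
        graph = Graph()
        fido = _uri("fido", DATA)
        graph.add((fido, RDF.type, _uri("Dog")))
        graph.add((fido, _uri("name"), Literal("fido")))
        box = BNode()
        graph.add((fido, _uri("ranks"), box))
        graph.add((box, URIRef(str(RDF) + "_1"), Literal(1)))
        # two objects for the same unknown predicate -> one violation
        graph.add((fido, _uri("agee"), Literal(1)))
        graph.add((fido, _uri("agee"), Literal(2)))
        report = validate_graph(graph, zoo_schema)
        assert len(report.violations) == 1

    def test_unparseable_data_is_input_error(self, zoo_schema, tmp_path):
        bad = tmp_path / "bad.ttl"
        bad.write_text("this is not turtle @@@")
        with pytest.raises(InputError):
            validate_graph(bad, zoo_schema)

    def test_report_serializations(self, conforming_zoo_graph, zoo_schema):
        import json
        conforming_zoo_graph.remove((_uri("fido", DATA), _uri("name"), None))
        report = validate_graph(conforming_zoo_graph, zoo_schema)
        payload = json.loads(report.to_json())
        assert payload["conforms"] is False
        assert payload["violations"][0]["kind"] == "missing_required"
        assert "missing_required" in report.to_text()
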