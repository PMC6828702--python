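"""The genomic-locations fixture: structural fidelity, the GenBank
location codec (with Biopython as independent oracle), the strand rule,
provenance extension, and the bundled toy annotation."""

import pytest
from rdflib import Graph

from empusa.emit import emit_owl, emit_shex
from empusa.errors import (
    DanglingReference,
    DuplicateProperty,
    ExtensionError,
    LocationSyntaxError,
)
from empusa.gbol import (
    GBOL,
    LOCATIONS_MANIFEST,
    build_toy_annotation,
    build_toy_annotation_from_gff3,
    decode_location,
    encode_location,
    extend_with_provenance_subclass,
    new_annotation_store,
    parse_location_string,
    strand_rule_check,
    write_fixture_files,
)
from empusa.model import (
    AnnotationSet,
    ClassDef,
    PropertyDef,
    REQUIRED,
    TargetRef,
)
from empusa.reader import emit_definition, parse_schema
from empusa.runtime import export_graph
from empusa.shexc import validate_with_engine
from empusa.validate import ViolationKind, validate_graph

#: Canonical strings covering every location class of the fixture.
ROUND_TRIP_STRINGS = [
    "100..200", "5..5", "467", "102^103",
    "<5..10", "5..>10", "<5..>10",
    "(102.110)..200", "one-of(3,5,9)..20", "102.110", "one-of(3,5)",
    "complement(300..400)", "complement(1..9)",
    "join(500..550,600..650)", "order(10..20,30..40)",
    "complement(join(10..20,30..40))",
    "gap()", "gap(43)",
]


@pytest.fixture
def dna_store(gbol_api):
    store = new_annotation_store()
    chromosome = gbol_api.Sequence(store, iri=GBOL + "i/chr1")
    chromosome.set_sequence("ACGTACGT")
    chromosome.set_strandType(gbol_api.Strandedness.DoubleStrandedDNA)
    return store


@pytest.fixture
def protein_store(gbol_api):
    store = new_annotation_store()
    protein = gbol_api.Sequence(store, iri=GBOL + "i/protA")
    protein.set_sequence("MKVLA")
    protein.set_strandType(gbol_api.Strandedness.Protein)
    return store


class TestStructure:
    def test_table_counts(self, locations_schema):
        assert tuple(locations_schema.stats()) == (16, 17, 1)
        assert LOCATIONS_MANIFEST["counts"] == \
            {"classes": 16, "properties": 17, "value_sets": 1}

    @pytest.mark.parametrize("name", ["BaseLocation", "InBetweenLocation",
                                      "CollectionOfRegions", "Region"])
    def test_location_children(self, locations_schema, name):
        assert locations_schema.classes[GBOL + name].parent == GBOL + "Location"

    def test_strand_position_is_not_under_position(self, locations_schema):
        position_tree = {GBOL + "Position"} | \
            locations_schema.descendants(GBOL + "Position")
        assert GBOL + "StrandPosition" not in position_tree
        assert GBOL + "StrandPosition" in locations_schema.value_sets

    def test_strand_members(self, locations_schema):
        assert locations_schema.value_set_members(GBOL + "StrandPosition") == {
            GBOL + "ForwardStrandPosition", GBOL + "ReverseStrandPosition",
            GBOL + "BothStrandsPosition"}

    def test_fuzzy_positions_hold_integers_not_positions(self,
                                                         locations_schema):
        for name in ("BeforePosition", "AfterPosition", "OneOfPosition"):
            (prop,) = locations_schema.classes[GBOL + name].properties
            assert prop.target.datatype == "integer"

    def test_no_terminal_classes_or_reflective_properties(self,
                                                          locations_schema):
        names = {c.name for c in locations_schema.classes.values()}
        assert not {n for n in names if "Terminal" in n}
        prop_names = {p.name for c in locations_schema.classes.values()
                      for p in c.properties}
        assert "beginOf" not in prop_names and "endOf" not in prop_names

    def test_reference_sits_on_location_not_position(self, locations_schema):
        assert any(p.name == "reference" for p in
                   locations_schema.classes[GBOL + "Location"].properties)
        for iri in {GBOL + "Position"} | \
                locations_schema.descendants(GBOL + "Position"):
            assert all(p.name != "reference"
                       for p in locations_schema.effective_properties(iri))

    def test_before_position_child_effective_properties(self,
                                                        locations_schema):
        names = [p.name for p in
                 locations_schema.effective_properties(GBOL + "BeforePosition")]
        assert names == ["position"]

    def test_nucleic_acid_value_set(self, demo_schema):
        members = demo_schema.value_set_members(GBOL + "NucleicAcid")
        assert {m.rsplit("/", 1)[-1] for m in members} == \
            {"Adenine", "Cytosine", "Guanine", "Thiamine", "Uracil", "Inosine"}

    def test_file_type_value_set(self, demo_schema):
        members = demo_schema.value_set_members(GBOL + "FileType")
        assert {m.rsplit("/", 1)[-1] for m in members} == {"CSV", "TXT", "TSV"}


class TestLocationCodec:
    @pytest.mark.parametrize("text", ROUND_TRIP_STRINGS)
    def test_decode_encode_round_trip(self, text, dna_store):
        iri = encode_location(text, GBOL + "i/chr1", dna_store)
        assert decode_location(dna_store, iri) == text

    def test_in_between_semantics(self, dna_store, gbol_api):
        iri = encode_location("102^103", GBOL + "i/chr1", dna_store)
        location = dna_store.get(iri)
        assert location.CLASS_IRI == GBOL + "InBetweenLocation"
        assert location.get_after().get_position() == 102

    def test_in_between_requires_adjacent_bases(self, dna_store):
        with pytest.raises(LocationSyntaxError):
            encode_location("102^104", GBOL + "i/chr1", dna_store)

    def test_join_builds_ordered_collection(self, dna_store):
        iri = encode_location("join(10..20,30..40)", GBOL + "i/chr1",
                              dna_store)
        collection = dna_store.get(iri)
        assert collection.CLASS_IRI == GBOL + "OrderedCollectionOfRegions"
        begins = [m.get_begin().get_position()
                  for m in collection.get_memberRegions()]
        assert begins == [10, 30]

    def test_complement_sets_reverse_strand(self, dna_store):
        iri = encode_location("complement(1..9)", GBOL + "i/chr1", dna_store)
        assert dna_store.get(iri).get_strand() == \
            GBOL + "ReverseStrandPosition"

    def test_single_base_interval(self, dna_store):
        iri = encode_location("5..5", GBOL + "i/chr1", dna_store)
        region = dna_store.get(iri)
        assert region.get_begin().get_position() == 5
        assert region.get_end().get_position() == 5

    @pytest.mark.parametrize("bad", ["", "..5", "10..", "join()", "5..x",
                                     "complement(", "one-of()", "10...20"])
    def test_malformed_strings_rejected(self, bad, dna_store):
        with pytest.raises(LocationSyntaxError):
            encode_location(bad, GBOL + "i/chr1", dna_store)

    def test_unregistered_sequence_rejected(self, gbol_api):
        with pytest.raises(DanglingReference):
            encode_location("1..2", GBOL + "i/ghost", new_annotation_store())

    @pytest.mark.parametrize("text,start,end,strand", [
        ("100..200", 99, 200, 1),
        ("complement(300..400)", 299, 400, -1),
        ("<5..10", 4, 10, 1),
        ("102^103", 102, 102, 1),
    ])
    def test_positions_agree_with_biopython(self, text, start, end, strand,
                                            dna_store):
        """Independent oracle: Biopython's GenBank location parser agrees
        on the (0-based, half-open) span and strand."""
        from Bio.SeqFeature import SimpleLocation
        oracle = SimpleLocation.fromstring(text)
        assert (int(oracle.start), int(oracle.end)) == (start, end)
        assert (oracle.strand or 1) == strand
        iri = encode_location(text, GBOL + "i/chr1", dna_store)
        location = dna_store.get(iri)
        if location.CLASS_IRI == GBOL + "Region":
            begin = location.get_begin()
            value = begin.get_position()
            # our model is 1-based fully closed: begin-1 == oracle.start
            assert value - 1 == int(oracle.start)
            assert location.get_end().get_position() == int(oracle.end)
            expected = -1 if location.get_strand() == \
                GBOL + "ReverseStrandPosition" else 1
            assert expected == (oracle.strand or 1)


class TestStrandRule:
    def test_stranded_region_on_protein_is_violation(self, protein_store):
        encode_location("complement(1..2)", GBOL + "i/protA", protein_store)
        violations = strand_rule_check(protein_store)
        assert [v.kind for v in violations] == [ViolationKind.STRAND_RULE]

    def test_stranded_region_on_double_stranded_dna_is_fine(self, dna_store):
        encode_location("complement(1..2)", GBOL + "i/chr1", dna_store)
        assert strand_rule_check(dna_store) == []

    def test_unstranded_location_on_protein_is_fine(self, protein_store):
        encode_location("1..2", GBOL + "i/protA", protein_store)
        encode_location("3", GBOL + "i/protA", protein_store)
        assert strand_rule_check(protein_store) == []

    def test_exhaustive_kind_table(self, gbol_api):
        """All (location strandedness x sequence kind) combinations."""
        cases = {"DoubleStrandedDNA": False, "SingleStrandedDNA": True,
                 "RNA": True, "Protein": True}
        for kind, stranded_is_violation in cases.items():
            store = new_annotation_store()
            seq_iri = GBOL + f"i/seq{kind}"
            sequence = gbol_api.Sequence(store, iri=seq_iri)
            sequence.set_sequence("ACGT")
            sequence.set_strandType(getattr(gbol_api.Strandedness, kind))
            encode_location("complement(1..2)", seq_iri, store)  # stranded
            encode_location("1..2", seq_iri, store)              # plain
            found = strand_rule_check(store)
            assert len(found) == (1 if stranded_is_violation else 0), kind

    def test_dangling_reference_raises(self, gbol_api, dna_store):
        region = gbol_api.Region(dna_store)
        begin = gbol_api.ExactPosition(dna_store)
        begin.set_position(1)
        region.set_begin(begin)
        region.set_end(begin)
        region.set_strand(GBOL + "ForwardStrandPosition")
        region.set_reference("http://elsewhere.example.org/chrX")
        with pytest.raises(DanglingReference):
            strand_rule_check(dna_store)


class TestProvenanceExtension:
    def _blast(self):
        return ClassDef(
            iri=GBOL + "Blast", name="Blast",
            parent=GBOL + "ProvenanceAnnotation",
            annotations=AnnotationSet(definition="BLAST evidence."),
            properties=(PropertyDef("bitScore", GBOL + "bitScore",
                                    TargetRef.primitive("double"), REQUIRED),))

    def test_extended_schema_accepts_blast_instances(self, demo_schema):
        from rdflib import Literal, URIRef
        from rdflib.namespace import RDF, XSD
        extended = extend_with_provenance_subclass(demo_schema, self._blast())
        graph = Graph()
        node = URIRef(GBOL + "i/blast1")
        graph.add((node, RDF.type, URIRef(GBOL + "Blast")))
        graph.add((node, URIRef(GBOL + "bitScore"),
                   Literal(88.5, datatype=XSD.double)))
        assert validate_graph(graph, extended).conforms
        # the unextended schema reports the type as foreign
        report = validate_graph(graph, demo_schema)
        assert report.kinds() == {ViolationKind.NON_SCHEMA_TYPE}
        # and the original schema object is untouched
        assert GBOL + "Blast" not in demo_schema.classes

    def test_wrong_parent_rejected(self, demo_schema):
        rogue = ClassDef(
            iri=GBOL + "Rogue", name="Rogue", parent=GBOL + "Feature",
            annotations=AnnotationSet(definition="Wrongly parented."))
        with pytest.raises(ExtensionError):
            extend_with_provenance_subclass(demo_schema, rogue)

    def test_duplicate_property_versus_parent_rejected(self, demo_schema):
        clash = ClassDef(
            iri=GBOL + "Clash", name="Clash",
            parent=GBOL + "ProvenanceAnnotation",
            annotations=AnnotationSet(definition="Redefines experiment."),
            properties=(PropertyDef("experiment", GBOL + "experiment",
                                    TargetRef.primitive("string"), REQUIRED),))
        with pytest.raises(DuplicateProperty):
            extend_with_provenance_subclass(demo_schema, clash)


class TestToyAnnotation:
    def test_toy_graph_conforms_and_passes_emitted_shex(self, demo_schema):
        store = build_toy_annotation()
        text = export_graph(store)
        graph = Graph()
        graph.parse(data=text, format="turtle")
        assert validate_graph(graph, demo_schema).conforms
        ok, failures = validate_with_engine(emit_shex(demo_schema).content,
                                            graph, GBOL)
        assert ok, failures

    def test_every_feature_has_reachable_provenance(self, gbol_api):
        store = build_toy_annotation()
        features = [i for i in store if i.CLASS_IRI == GBOL + "Feature"]
        assert len(features) == 3
        for feature in features:
            (prov,) = feature.get_provenance()
            assert prov.get_onProperty() == GBOL + "location"
            activity = prov.get_derivedFrom()
            assert activity.get_softwareAgent()
            assert activity.get_parameter()

    def test_gff3_route_matches_gbk_route(self):
        """The same three genes load from GFF3 and from the location
        strings; the decoded location strings coincide."""
        def locations(store):
            out = {}
            for instance in store:
                if instance.CLASS_IRI == GBOL + "Feature":
                    name = instance.iri.rsplit("/", 1)[-1]
                    out[name] = decode_location(store,
                                                instance.get_location().iri)
            return out
        assert locations(build_toy_annotation()) == \
            locations(build_toy_annotation_from_gff3())

    def test_fixture_files_write_and_reload(self, tmp_path, locations_schema,
                                            demo_schema):
        paths = {p.name for p in write_fixture_files(tmp_path)}
        assert {"gbol_locations.ttl", "demo_annotation.ttl",
                "toy_genome.gbk-loc", "toy_genome.gff3", "toy_instances.ttl",
                "locations_manifest.json"} <= paths
        reloaded = parse_schema(tmp_path / "gbol_locations.ttl")
        assert tuple(reloaded.stats()) == (16, 17, 1)
        assert emit_definition(reloaded) == \
            (tmp_path / "gbol_locations.ttl").read_text()
        demo_reloaded = parse_schema(tmp_path / "demo_annotation.ttl")
        report = validate_graph(tmp_path / "toy_instances.ttl", demo_reloaded)
        assert report.conforms

    def test_fixture_passes_all_emitters(self, locations_schema):
        from empusa.codegen import generate_api
        from empusa.docs import generate_docs
        assert emit_owl(locations_schema).content
        assert emit_shex(locations_schema).content
        assert generate_docs(locations_schema)
        assert generate_api(locations_schema)
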