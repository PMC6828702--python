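"""Materialize the bundled fixture files and the toy annotation graph.

The toy annotation encodes a 1 kb double-stranded chromosome with three
genes (forward, reverse-strand, and a two-exon join), wrapped in a
document/data-set pair and full provenance: one automatic annotation
activity (software agent, parameters, output file) and one
FeatureProvenance node per feature location.
"""

from __future__ import annotations

import json
import random
from importlib import resources
from pathlib import Path

from ..reader import emit_definition
from ..runtime import InstanceStore, export_graph
from .demo import build_demo_schema
from .genbank import encode_location, get_api, new_annotation_store
from .locations import GBOL, LOCATIONS_MANIFEST, build_locations_schema

CHROMOSOME_IRI = GBOL + "instance/toy/chr1"
PRODIGAL_IRI = "https://github.com/hyattpd/Prodigal"


def _data_text(name: str) -> str:
    return (resources.files("empusa.gbol") / "data" / name).read_text()


def read_toy_locations() -> list:
    """(feature id, feature key, location string) triples of the toy
    annotation input."""
    rows = []
    for line in _data_text("toy_genome.gbk-loc").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        feature_id, key, location = line.split("\t")
        rows.append((feature_id, key, location))
    return rows


def read_toy_gff3() -> list:
    """Toy GFF3 records as (seqid, source, type, start, end, strand, attrs)."""
    records = []
    for line in _data_text("toy_genome.gff3").splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, source, ftype, start, end, _score, strand, _phase, attrs = \
            line.split("\t")
        attributes = dict(part.split("=", 1) for part in attrs.split(";"))
        records.append((seqid, source, ftype, int(start), int(end), strand,
                        attributes))
    return records


def _toy_sequence(length: int = 1000) -> str:
    rng = random.Random(1000)
    return "".join(rng.choice("ACGT") for _ in range(length))


def build_toy_annotation() -> InstanceStore:
    """The bundled 3-gene toy annotation, built through the generated
    bindings (hence correct by construction)."""
    api = get_api()
    store = new_annotation_store()

    chromosome = api.Sequence(store, iri=CHROMOSOME_IRI)
    chromosome.set_sequence(_toy_sequence())
    chromosome.set_strandType(api.Strandedness.DoubleStrandedDNA)

    output = api.File(store)
    output.set_filename("toy_genes.tsv")
    output.set_fileType(api.FileType.TSV)
    activity = api.AutomaticAnnotationActivity(store)
    activity.set_softwareAgent(PRODIGAL_IRI)
    activity.add_parameter("-p single")
    activity.add_outputFile(output)

    for feature_id, key, location_string in read_toy_locations():
        feature = api.Feature(store, iri=GBOL + f"instance/toy/{feature_id}")
        feature.set_featureKey(key)
        location_iri = encode_location(location_string, CHROMOSOME_IRI, store)
        feature.set_location(store.get(location_iri))
        provenance = api.FeatureProvenance(store)
        provenance.set_onProperty(GBOL + "location")
        provenance.set_derivedFrom(activity)
        evidence = api.ProvenanceAnnotation(store)
        evidence.set_experiment("http://purl.obolibrary.org/obo/ECO_0000203")
        provenance.set_annotation(evidence)
        feature.add_provenance(provenance)
        chromosome.add_feature(feature)

    document = api.Document(store)
    document.set_title("Toy genome annotation")
    document.set_describes(chromosome)
    dataset = api.GBOLDataSet(store)
    dataset.set_name("toy")
    dataset.add_document(document)
    dataset.add_activity(activity)
    return store


def build_toy_annotation_from_gff3() -> InstanceStore:
    """Same toy annotation, driven by the GFF3 records instead of the
    GenBank location strings (multi-part features become joins)."""
    parts: dict = {}
    order: list = []
    for seqid, _src, _type, start, end, strand, attrs in read_toy_gff3():
        feature_id = attrs["ID"]
        if feature_id not in parts:
            parts[feature_id] = []
            order.append(feature_id)
        span = f"{start}..{end}"
        parts[feature_id].append(f"complement({span})" if strand == "-" else span)

    api = get_api()
    store = new_annotation_store()
    chromosome = api.Sequence(store, iri=CHROMOSOME_IRI)
    chromosome.set_sequence(_toy_sequence())
    chromosome.set_strandType(api.Strandedness.DoubleStrandedDNA)
    for feature_id in order:
        spans = parts[feature_id]
        location_string = spans[0] if len(spans) == 1 else \
            "join(" + ",".join(spans) + ")"
        feature = api.Feature(store, iri=GBOL + f"instance/toy/{feature_id}")
        feature.set_featureKey("gene")
        feature.set_location(
            store.get(encode_location(location_string, CHROMOSOME_IRI, store)))
        chromosome.add_feature(feature)
    return store


def write_fixture_files(out_dir) -> list:
    """Write the bundled fixture set; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(name: str, text: str):
        path = out / name
        path.write_text(text, encoding="utf-8")
        written.append(path)

    emit("gbol_locations.ttl", emit_definition(build_locations_schema()))
    emit("demo_annotation.ttl", emit_definition(build_demo_schema()))
    emit("toy_genome.gbk-loc", _data_text("toy_genome.gbk-loc"))
    emit("toy_genome.gff3", _data_text("toy_genome.gff3"))
    emit("toy_instances.ttl", export_graph(build_toy_annotation()))
    emit("locations_manifest.json",
         json.dumps(LOCATIONS_MANIFEST, indent=2) + "\n")
    return written
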