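"""Reduced feature / document / provenance demo schema.

Extends the genomic-locations sub-ontology with the minimal surrounding
vocabulary: sequences have features, features have locations on the
sequence, and every annotation is traceable — dataset-wise through
annotation activities (automatic ones must name a software agent,
parameters and input/output files; manual ones a curator), element-wise
through per-feature-property ``FeatureProvenance`` nodes whose
tool-specific scores live in user-defined ``ProvenanceAnnotation``
subclasses (those subclasses are extensions, not part of the schema
itself).
"""

from __future__ import annotations

from ..errors import ExtensionError
from ..model import (
    ANY,
    AT_LEAST_ONE,
    AnnotationSet,
    ClassDef,
    OPTIONAL,
    PropertyDef,
    REQUIRED,
    Schema,
    TargetRef,
    ValueSetDef,
)
from .locations import GBOL, build_locations_schema


def _prop(name, target, mult, description):
    return PropertyDef(name=name, iri=GBOL + name, target=target,
                       multiplicity=mult, description=description)


def _cls(name, definition, parent=None, properties=(), **ann):
    return ClassDef(iri=GBOL + name, name=name,
                    parent=GBOL + parent if parent else None,
                    properties=tuple(properties),
                    annotations=AnnotationSet(definition=definition, **ann))


def build_demo_schema() -> Schema:
    """Locations sub-ontology plus the feature/document/provenance demo."""
    locations = build_locations_schema()
    string = TargetRef.primitive("string")

    classes = [
        _cls("Sequence",
             "A biological sequence carrying features; its strand type "
             "decides whether locations on it may be stranded.",
             properties=[
                 _prop("sequence", string, REQUIRED,
                       "the residue string; exactly one per sequence"),
                 _prop("strandType", TargetRef.value_set(GBOL + "Strandedness"),
                       REQUIRED, "physical strandedness of the molecule"),
                 _prop("feature", TargetRef.class_ref(GBOL + "Feature"), ANY,
                       "features annotated on this sequence"),
             ]),
        _cls("Feature",
             "An annotated element located on a sequence.",
             ddbj_label="misc_feature",
             properties=[
                 _prop("location", TargetRef.class_ref(GBOL + "Location"),
                       REQUIRED, "genomic location of the feature"),
                 _prop("featureKey", string, REQUIRED,
                       "feature-table key, e.g. gene or CDS"),
                 _prop("provenance",
                       TargetRef.class_ref(GBOL + "FeatureProvenance"), ANY,
                       "element-wise provenance, per property per feature"),
             ]),
        _cls("Document",
             "Single packaging entity holding all annotations of one "
             "sequence.",
             properties=[
                 _prop("describes", TargetRef.class_ref(GBOL + "Sequence"),
                       REQUIRED, "the sequence the document packages"),
                 _prop("title", string, OPTIONAL, "human-readable title"),
             ]),
        _cls("GBOLDataSet",
             "A data collection: metadata plus references to the documents "
             "and annotation activities it contains.",
             properties=[
                 _prop("name", string, REQUIRED, "name of the data set"),
                 _prop("document", TargetRef.class_ref(GBOL + "Document"),
                       ANY, "documents in the collection"),
                 _prop("activity",
                       TargetRef.class_ref(GBOL + "AnnotationActivity"), ANY,
                       "annotation activities that produced the collection"),
             ]),
        _cls("AnnotationActivity",
             "Dataset-wise provenance: one annotation run over the "
             "collection (PROV-O Activity).",
             exact_matches={"http://www.w3.org/ns/prov#Activity"}),
        _cls("AutomaticAnnotationActivity",
             "An automatic annotation: must name its software agent, its "
             "parameters and the files it read and/or wrote.",
             parent="AnnotationActivity",
             properties=[
                 _prop("softwareAgent", TargetRef.external(), REQUIRED,
                       "IRI of the software agent that ran"),
                 _prop("parameter", string, AT_LEAST_ONE,
                       "parameter settings of the run"),
                 _prop("inputFile", TargetRef.class_ref(GBOL + "File"), ANY,
                       "files the run consumed"),
                 _prop("outputFile", TargetRef.class_ref(GBOL + "File"), ANY,
                       "files the run produced"),
             ]),
        _cls("ManualAnnotationActivity",
             "A manual curation: must name its curator.",
             parent="AnnotationActivity",
             properties=[
                 _prop("curator", TargetRef.external(), REQUIRED,
                       "IRI of the curator (FOAF person)"),
             ]),
        _cls("File",
             "A file read or written by an annotation activity.",
             properties=[
                 _prop("filename", string, REQUIRED, "file name"),
                 _prop("fileType", TargetRef.value_set(GBOL + "FileType"),
                       REQUIRED, "format of the file"),
             ]),
        _cls("FeatureProvenance",
             "Element-wise provenance: binds one property of one feature to "
             "the activity and evidence that produced it.",
             properties=[
                 _prop("onProperty", TargetRef.external(), REQUIRED,
                       "IRI of the feature property this provenance covers"),
                 _prop("derivedFrom",
                       TargetRef.class_ref(GBOL + "AnnotationActivity"),
                       REQUIRED, "the activity that produced the value"),
                 _prop("annotation",
                       TargetRef.class_ref(GBOL + "ProvenanceAnnotation"),
                       OPTIONAL, "tool-specific evidence record"),
             ]),
        _cls("ProvenanceAnnotation",
             "Extensible base for tool-specific confidence records (Blast, "
             "HMM, SignalP, ...); concrete subclasses are user extensions.",
             properties=[
                 _prop("experiment", TargetRef.external(), OPTIONAL,
                       "evidence-ontology term the annotation is based on"),
             ]),
    ]

    value_sets = [
        ValueSetDef(
            iri=GBOL + "Strandedness", name="Strandedness",
            members={GBOL + "DoubleStrandedDNA": None,
                     GBOL + "SingleStrandedDNA": None,
                     GBOL + "RNA": None,
                     GBOL + "Protein": None},
            annotations=AnnotationSet(
                definition="Physical strandedness of a sequence; only "
                           "double-stranded DNA admits stranded locations."),
        ),
        ValueSetDef(
            iri=GBOL + "FileType", name="FileType",
            members={GBOL + "CSV": None, GBOL + "TXT": None, GBOL + "TSV": None},
            annotations=AnnotationSet(definition="File format of an "
                                                 "activity's input/output."),
        ),
        ValueSetDef(
            iri=GBOL + "NucleicAcid", name="NucleicAcid",
            members={GBOL + "Adenine": None, GBOL + "Cytosine": None,
                     GBOL + "Guanine": None, GBOL + "Thiamine": None,
                     GBOL + "Uracil": None, GBOL + "Inosine": None},
            annotations=AnnotationSet(
                definition="Nucleic-acid bases; a value set that could "
                           "evolve into a full sub-ontology."),
        ),
    ]

    classes_map = dict(locations.classes)
    classes_map.update({c.iri: c for c in classes})
    value_sets_map = dict(locations.value_sets)
    value_sets_map.update({v.iri: v for v in value_sets})
    return Schema(base_iri=GBOL, classes=classes_map,
                  value_sets=value_sets_map, prefixes=dict(locations.prefixes))


def extend_with_provenance_subclass(schema: Schema,
                                    subclass_def: ClassDef) -> Schema:
    """Return a copy of ``schema`` extended with a tool-specific
    ProvenanceAnnotation subclass; the input schema is left untouched."""
    anchor = GBOL + "ProvenanceAnnotation"
    if subclass_def.parent != anchor:
        raise ExtensionError(
            f"extension class {subclass_def.name} must subclass "
            f"<{anchor}>, not <{subclass_def.parent}>"
        )
    classes = dict(schema.classes)
    classes[subclass_def.iri] = subclass_def
    return Schema(base_iri=schema.base_iri, classes=classes,
                  value_sets=dict(schema.value_sets),
                  prefixes=dict(schema.prefixes))
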