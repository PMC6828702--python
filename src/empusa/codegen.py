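"""Generate a typed Python data-binding API from a Schema.

One source module is produced per class and per value set, mirroring the
schema's inheritance in Python inheritance; value sets become ``Enum``
classes whose values are member IRIs.  Data built through the bindings is
correct by construction: setters type-check their argument, single-valued
setters overwrite, multi-valued adders append, and the store export
(:func:`empusa.runtime.export_graph`) re-verifies everything before
serializing.

Generation is template-driven and deterministic; a ``manifest.json``
lists the generated units together with a checksum of the schema they
were generated from.
"""

from __future__ import annotations

import hashlib
import importlib.util
import json
import keyword
import logging
import re
import sys
from pathlib import Path
from typing import Optional

from .emit import GeneratedArtifact
from .model import OrderedKind, Schema, TargetKind
from .reader import emit_definition

logger = logging.getLogger(__name__)

_HEADER = "# Generated data binding; do not edit by hand.\n"


def _snake(name: str) -> str:
    return re.sub(r"(?<!^)(?=[A-Z])", "_", name).lower()


def _safe(name: str) -> str:
    """Escape host-language reserved words with a trailing underscore."""
    if keyword.iskeyword(name):
        logger.warning("renaming reserved word %r to %r", name, name + "_")
        return name + "_"
    return name


def schema_checksum(schema: Schema) -> str:
    return hashlib.sha256(emit_definition(schema).encode("utf-8")).hexdigest()


def _value_set_module(vs) -> str:
    lines = [_HEADER, "import enum", "", ""]
    lines.append(f"class {_safe(vs.name)}(enum.Enum):")
    doc = vs.annotations.definition if vs.annotations else f"Value set {vs.name}."
    lines.append(f'    """{doc}"""')
    lines.append("")
    for member in sorted(vs.members):
        local = member.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
        lines.append(f'    {_safe(local)} = "{member}"')
    return "\n".join(lines) + "\n"


def _accessor_block(prop) -> list:
    name = prop.name
    doc = prop.description or f"Property '{name}' ({prop.multiplicity.token()})."
    lines: list = []
    if prop.multiplicity.unbounded:
        lines += [
            f"    def add_{name}(self, value):",
            f'        """{doc}"""',
            f'        self._add("{name}", value)',
            "",
            f"    def remove_{name}(self, value):",
            f'        self._remove("{name}", value)',
            "",
            f"    def get_{name}(self):",
            f'        return self._get("{name}")',
            "",
        ]
    else:
        lines += [
            f"    def set_{name}(self, value):",
            f'        """{doc}"""',
            f'        self._set("{name}", value)',
            "",
            f"    def get_{name}(self):",
            f'        return self._get("{name}")',
            "",
        ]
    return lines


def _class_module(schema: Schema, cls) -> str:
    lines = [_HEADER]
    if cls.parent is None:
        lines.append("from empusa.runtime import Instance")
        parent_name = "Instance"
    else:
        parent = schema.classes[cls.parent]
        lines.append(f"from .{_snake(parent.name)} import {_safe(parent.name)}")
        parent_name = _safe(parent.name)
    lines += ["", ""]
    lines.append(f"class {_safe(cls.name)}({parent_name}):")
    lines.append(f'    """{cls.annotations.definition}"""')
    lines.append("")
    lines.append(f'    CLASS_IRI = "{cls.iri}"')
    lines.append("")
    if not cls.properties:
        lines[-1:] = []  # no trailing blank before end of empty body
    for prop in cls.properties:
        lines.extend(_accessor_block(prop))
    return "\n".join(lines).rstrip() + "\n"


def _schema_module(schema: Schema) -> str:
    text = emit_definition(schema)
    escaped = text.replace("\\", "\\\\").replace('"""', '\\"\\"\\"')
    return (
        _HEADER
        + "from rdflib import Graph\n\n"
        + "from empusa.reader import parse_schema\n"
        + "from empusa.runtime import InstanceStore\n\n"
        + f'SCHEMA_TURTLE = """{escaped}"""\n\n'
        + "_graph = Graph(bind_namespaces=\"core\")\n"
        + '_graph.parse(data=SCHEMA_TURTLE, format="turtle")\n'
        + "SCHEMA = parse_schema(_graph)\n\n\n"
        + "def new_store():\n"
        + '    """Fresh instance store bound to this binding\'s schema."""\n'
        + "    return InstanceStore(SCHEMA)\n"
    )


def generate_api(schema: Schema, out_dir: Optional[Path] = None) -> list:
    """Generate the binding package; optionally write it under ``out_dir``.

    Returns the list of :class:`GeneratedArtifact` units (one per class,
    one per value set, plus ``schema.py``, ``__init__.py`` and the
    manifest).
    """
    artifacts: list = []
    exported: list = []

    for iri in sorted(schema.classes):
        cls = schema.classes[iri]
        artifacts.append(GeneratedArtifact(
            kind="source", path=f"{_snake(cls.name)}.py",
            content=_class_module(schema, cls)))
        exported.append((_snake(cls.name), _safe(cls.name)))
    for iri in sorted(schema.value_sets):
        vs = schema.value_sets[iri]
        artifacts.append(GeneratedArtifact(
            kind="source", path=f"{_snake(vs.name)}.py",
            content=_value_set_module(vs)))
        exported.append((_snake(vs.name), _safe(vs.name)))

    artifacts.append(GeneratedArtifact(kind="source", path="schema.py",
                                       content=_schema_module(schema)))

    init = [_HEADER]
    init.append("from .schema import SCHEMA, new_store")
    for module, symbol in exported:
        init.append(f"from .{module} import {symbol}")
    init.append("")
    init.append("__all__ = [\"SCHEMA\", \"new_store\", "
                + ", ".join(f'"{symbol}"' for _, symbol in exported) + "]")
    artifacts.append(GeneratedArtifact(kind="source", path="__init__.py",
                                       content="\n".join(init) + "\n"))

    manifest = {
        "schema_checksum": schema_checksum(schema),
        "units": [a.path for a in artifacts],
    }
    artifacts.append(GeneratedArtifact(
        kind="config", path="manifest.json",
        content=json.dumps(manifest, indent=2) + "\n"))

    if out_dir is not None:
        for artifact in artifacts:
            artifact.write(out_dir)
    return artifacts


def load_api(schema: Schema, out_dir: Path):
    """Generate the binding package into ``out_dir`` and import it.

    The package name embeds the schema checksum, so loading the same
    schema twice reuses the already-imported module.
    """
    package = f"empusa_api_{schema_checksum(schema)[:12]}"
    if package in sys.modules:
        return sys.modules[package]
    out = Path(out_dir) / package
    generate_api(schema, out)
    spec = importlib.util.spec_from_file_location(
        package, out / "__init__.py",
        submodule_search_locations=[str(out)])
    module = importlib.util.module_from_spec(spec)
    sys.modules[package] = module
    spec.loader.exec_module(module)
    return module
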