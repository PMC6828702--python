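"""Generate browsable Markdown documentation for a Schema.

The page layout mirrors the IRI namespace — ``<out>/<ClassName>/index.md``
— so a static site served at the schema's base IRI makes every class IRI
resolve to its own documentation page.  An ``index.md`` with the class
tree and an mkdocs-compatible site configuration are emitted alongside.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

from .emit import GeneratedArtifact
from .model import Schema, TargetKind


def _target_cell(schema: Schema, prop) -> str:
    t = prop.target
    if t.kind is TargetKind.PRIMITIVE:
        return f"`xsd:{t.datatype}`"
    if t.kind is TargetKind.EXTERNAL_IRI:
        from .model import ANY_IRI
        if t.target_iri == ANY_IRI:
            return "`IRI` (external resource)"
        return f"[external IRI]({t.target_iri})"
    if t.kind is TargetKind.VALUE_SET_REF:
        name = schema.value_sets[t.target_iri].name
        return f"[@{name}](../{name}/index.md)"
    name = schema.classes[t.target_iri].name
    return f"[{name}](../{name}/index.md)"


def _property_table(schema: Schema, props) -> list:
    lines = ["| Property | Target | Multiplicity | Description |",
             "| --- | --- | --- | --- |"]
    for prop in props:
        anchor = f'<a id="{prop.name}"></a>'
        lines.append(
            f"| {anchor}`{prop.name}` | {_target_cell(schema, prop)} "
            f"| `{prop.multiplicity.token()}` | {prop.description or ''} |"
        )
    return lines


def _class_page(schema: Schema, cls) -> str:
    lines = [f"# {cls.name}", "", cls.annotations.definition, "",
             f"**IRI:** `{cls.iri}`", ""]
    if cls.parent is not None:
        parent = schema.classes[cls.parent]
        lines += [f"**Parent:** [{parent.name}](../{parent.name}/index.md)", ""]
    children = sorted(c.name for c in schema.classes.values()
                      if c.parent == cls.iri)
    if children:
        links = ", ".join(f"[{n}](../{n}/index.md)" for n in children)
        lines += [f"**Children:** {links}", ""]
    if cls.annotations.ddbj_label:
        lines += [f"**DDBJ / feature-table label:** `{cls.annotations.ddbj_label}`", ""]
    if cls.annotations.usage_comment:
        lines += [f"> {cls.annotations.usage_comment}", ""]
    if cls.annotations.editorial_comment:
        lines += [f"*Editorial note:* {cls.annotations.editorial_comment}", ""]
    if cls.annotations.exact_matches:
        lines.append("**Exact matches:** " + ", ".join(
            f"<{iri}>" for iri in sorted(cls.annotations.exact_matches)))
        lines.append("")
    if cls.properties:
        lines += ["## Properties", ""]
        lines += _property_table(schema, cls.properties)
        lines.append("")
    inherited = [(schema.classes[anc], schema.classes[anc].properties)
                 for anc in schema.ancestors(cls.iri)
                 if schema.classes[anc].properties]
    if inherited:
        lines += ["## Inherited properties", ""]
        for ancestor, props in inherited:
            lines += [f"### From [{ancestor.name}](../{ancestor.name}/index.md)", ""]
            lines += _property_table(schema, props)
            lines.append("")
    return "\n".join(lines).rstrip() + "\n"


def _value_set_page(schema: Schema, vs) -> str:
    lines = [f"# {vs.name}", ""]
    if vs.annotations is not None:
        lines += [vs.annotations.definition, ""]
    lines += [f"**IRI:** `{vs.iri}`", "",
              "A value set (controlled vocabulary); properties typed with it "
              "accept exactly the member IRIs below.", "", "## Members", ""]

    def render(parent, depth):
        for member in sorted(m for m, p in vs.members.items() if p == parent):
            local = member.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
            lines.append("    " * depth + f"- `{local}` — `{member}`")
            render(member, depth + 1)

    render(None, 0)
    lines.append("")
    return "\n".join(lines).rstrip() + "\n"


def _index_page(schema: Schema) -> str:
    lines = ["# Schema documentation", "",
             f"Namespace: `{schema.base_iri}`", "", "## Class tree", ""]

    def render(parent, depth):
        names = sorted(c.name for c in schema.classes.values()
                       if c.parent == parent)
        for name in names:
            lines.append("    " * depth + f"- [{name}]({name}/index.md)")
            render(schema.class_by_name(name).iri, depth + 1)

    render(None, 0)
    if schema.value_sets:
        lines += ["", "## Value sets", ""]
        for vs_iri in sorted(schema.value_sets):
            name = schema.value_sets[vs_iri].name
            lines.append(f"- [{name}]({name}/index.md)")
    lines.append("")
    return "\n".join(lines).rstrip() + "\n"


def _site_config(schema: Schema) -> str:
    nav = [{"Overview": "index.md"}]
    for name in sorted([c.name for c in schema.classes.values()]
                       + [v.name for v in schema.value_sets.values()]):
        nav.append({name: f"{name}/index.md"})
    config = {"site_name": f"Schema {schema.base_iri}",
              "docs_dir": "docs", "nav": nav}
    return yaml.safe_dump(config, sort_keys=False)


def generate_docs(schema: Schema, out_dir: Optional[Path] = None) -> list:
    """One Markdown page per class and value set, plus index and site
    configuration; regeneration is byte-identical for an unchanged schema."""
    artifacts = [GeneratedArtifact(kind="doc", path="docs/index.md",
                                   content=_index_page(schema))]
    for iri in sorted(schema.classes):
        cls = schema.classes[iri]
        artifacts.append(GeneratedArtifact(
            kind="doc", path=f"docs/{cls.name}/index.md",
            content=_class_page(schema, cls)))
    for iri in sorted(schema.value_sets):
        vs = schema.value_sets[iri]
        artifacts.append(GeneratedArtifact(
            kind="doc", path=f"docs/{vs.name}/index.md",
            content=_value_set_page(schema, vs)))
    artifacts.append(GeneratedArtifact(kind="config", path="mkdocs.yml",
                                       content=_site_config(schema)))
    if out_dir is not None:
        for artifact in artifacts:
            artifact.write(out_dir)
    return artifacts
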