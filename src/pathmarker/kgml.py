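"""KGML pathway parsing and conversion to gene-gene interaction edges.

KGML is the XML dialect in which KEGG distributes pathway diagrams.  The
elements that matter for network construction are:

``entry``
    a node of the diagram: a gene (possibly several KEGG gene ids sharing
    one box), a compound, a link to another map, or a ``group`` (a protein
    complex whose ``component`` children point at other entries);
``relation``
    a line between two entries, typed as ``ECrel`` (enzyme-enzyme),
    ``PPrel`` (protein-protein), ``GErel`` (gene expression), ``PCrel``
    (protein-compound) or ``maplink`` (link to another map).

:func:`pathway_edges` turns a parsed document into undirected gene-symbol
pairs: relations of the four gene-bearing types whose endpoints resolve
(after group expansion) to gene entries contribute the full bipartite
product of their gene sets; ``maplink`` relations and relations touching a
compound or map entry contribute nothing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree as ET

__all__ = [
    "KGMLEntry",
    "KGMLRelation",
    "KGMLGroup",
    "PathwayDoc",
    "KGMLParseError",
    "GENE_EDGE_RELATION_TYPES",
    "RELATION_TYPES",
    "parse_kgml",
    "parse_kgml_file",
    "write_kgml",
    "pathway_edges",
    "read_id_map",
    "write_id_map",
]

#: Relation types that can contribute a gene-gene edge.
GENE_EDGE_RELATION_TYPES = frozenset({"ECrel", "PPrel", "GErel", "PCrel"})

#: All relation types this dialect admits.
RELATION_TYPES = GENE_EDGE_RELATION_TYPES | {"maplink"}

ENTRY_TYPES = frozenset({"gene", "compound", "map", "group", "ortholog", "enzyme"})


class KGMLParseError(ValueError):
    """Raised when a KGML document violates the structural contract."""


@dataclass(frozen=True)
class KGMLEntry:
    """A pathway node: one diagram box, possibly naming several KEGG ids."""

    id: str
    type: str
    names: tuple[str, ...]
    display_name: str = ""


@dataclass(frozen=True)
class KGMLRelation:
    """A typed line between two entries, with KGML subtype annotations."""

    entry1: str
    entry2: str
    type: str
    subtypes: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class KGMLGroup:
    """A complex: a group entry together with its component entry ids."""

    id: str
    components: tuple[str, ...]


@dataclass
class PathwayDoc:
    """A parsed KGML pathway document."""

    pathway_id: str
    title: str
    entries: dict[str, KGMLEntry] = field(default_factory=dict)
    relations: list[KGMLRelation] = field(default_factory=list)
    groups: dict[str, KGMLGroup] = field(default_factory=dict)

    def gene_entries(self) -> list[KGMLEntry]:
        return [e for e in self.entries.values() if e.type == "gene"]


def parse_kgml(source: str | bytes) -> PathwayDoc:
    """Parse a KGML document from an XML string.

    Captures every ``entry``, ``relation`` and ``group`` element; unknown
    attributes (graphics, coordinates, links) are ignored.  Raises
    :class:`KGMLParseError` for malformed XML, a relation endpoint that does
    not resolve to an entry, or a group entry without components.
    """
    try:
        root = ET.fromstring(source)
    except ET.ParseError as exc:
        raise KGMLParseError(f"malformed XML: {exc}") from exc
    if root.tag != "pathway":
        raise KGMLParseError(f"root element is <{root.tag}>, expected <pathway>")

    doc = PathwayDoc(
        pathway_id=root.get("name", ""),
        title=root.get("title", ""),
    )

    for el in root.findall("entry"):
        entry_id = el.get("id")
        etype = el.get("type", "")
        if entry_id is None:
            raise KGMLParseError("entry without an id attribute")
        if entry_id in doc.entries:
            raise KGMLParseError(f"duplicate entry id {entry_id!r}")
        # multi-id boxes list whitespace-separated KEGG ids in @name
        names = tuple(el.get("name", "").split())
        graphics = el.find("graphics")
        display = graphics.get("name", "") if graphics is not None else ""
        doc.entries[entry_id] = KGMLEntry(
            id=entry_id, type=etype, names=names, display_name=display
        )
        if etype == "gene" and not names:
            raise KGMLParseError(f"gene entry {entry_id!r} has no KEGG ids")
        if etype == "group":
            components = tuple(
                c.get("id") for c in el.findall("component") if c.get("id")
            )
            if not components:
                raise KGMLParseError(f"group entry {entry_id!r} has no components")
            doc.groups[entry_id] = KGMLGroup(id=entry_id, components=components)

    for comp_group in doc.groups.values():
        for cid in comp_group.components:
            if cid not in doc.entries:
                raise KGMLParseError(
                    f"group {comp_group.id!r} references missing entry {cid!r}"
                )

    for el in root.findall("relation"):
        e1, e2 = el.get("entry1"), el.get("entry2")
        rtype = el.get("type", "")
        if rtype not in RELATION_TYPES:
            raise KGMLParseError(f"unknown relation type {rtype!r}")
        for endpoint in (e1, e2):
            if endpoint not in doc.entries:
                raise KGMLParseError(
                    f"relation endpoint {endpoint!r} does not resolve to an entry"
                )
        subtypes = tuple(
            (s.get("name", ""), s.get("value", "")) for s in el.findall("subtype")
        )
        doc.relations.append(
            KGMLRelation(entry1=e1, entry2=e2, type=rtype, subtypes=subtypes)
        )

    return doc


def parse_kgml_file(path: str | Path) -> PathwayDoc:
    """Parse a KGML document from a file path."""
    return parse_kgml(Path(path).read_bytes())


def write_kgml(doc: PathwayDoc) -> str:
    """Serialize a :class:`PathwayDoc` back to KGML XML.

    The output round-trips through :func:`parse_kgml` without loss of any
    field carried by the document model.  Serialization is deterministic:
    identical documents yield byte-identical strings.
    """
    lines = ['<?xml version="1.0" encoding="utf-8"?>']
    lines.append(
        f'<pathway name="{doc.pathway_id}" title="{doc.title}">'
    )
    for entry in doc.entries.values():
        name_attr = " ".join(entry.names)
        lines.append(
            f'  <entry id="{entry.id}" name="{name_attr}" type="{entry.type}">'
        )
        if entry.display_name:
            lines.append(f'    <graphics name="{entry.display_name}"/>')
        if entry.id in doc.groups:
            for cid in doc.groups[entry.id].components:
                lines.append(f'    <component id="{cid}"/>')
        lines.append("  </entry>")
    for rel in doc.relations:
        lines.append(
            f'  <relation entry1="{rel.entry1}" entry2="{rel.entry2}" type="{rel.type}">'
        )
        for name, value in rel.subtypes:
            lines.append(f'    <subtype name="{name}" value="{value}"/>')
        lines.append("  </relation>")
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"


def _entry_gene_symbols(
    doc: PathwayDoc,
    entry_id: str,
    id_map: Mapping[str, str],
    _expanding: frozenset[str] = frozenset(),
) -> set[str]:
    """Resolve an entry to the set of gene symbols it stands for.

    Gene entries map each KEGG id through ``id_map`` (ids absent from the
    map keep the KEGG id as node label); group entries expand to the union
    of their gene components; every other entry type resolves to the empty
    set.
    """
    entry = doc.entries[entry_id]
    if entry.type == "gene":
        return {id_map.get(kid, kid) for kid in entry.names}
    if entry.type == "group" and entry_id not in _expanding:
        symbols: set[str] = set()
        for cid in doc.groups[entry_id].components:
            symbols |= _entry_gene_symbols(
                doc, cid, id_map, _expanding | {entry_id}
            )
        return symbols
    return set()


@dataclass
class EdgeExtraction:
    """Edges extracted from one pathway plus bookkeeping counters."""

    edges: list[tuple[str, str, str]]  # (geneA, geneB, relation type), A < B
    n_relations: int = 0
    n_skipped: int = 0  # relations contributing no edge (maplink, non-gene ends)


def pathway_edges(
    doc: PathwayDoc,
    id_map: Mapping[str, str] | None = None,
    *,
    intra_group_edges: bool = False,
) -> EdgeExtraction:
    """Convert a pathway into undirected gene-pair edges.

    For every relation of type ECrel/PPrel/GErel/PCrel whose endpoints
    resolve (after group expansion) to non-empty gene sets A and B, all
    pairs A x B are emitted, excluding self-pairs.  ``maplink`` relations
    and relations with a compound/map endpoint are counted as skipped.

    With ``intra_group_edges=True``, complex co-membership also contributes
    edges: every pair of genes inside the same group is connected.
    """
    id_map = id_map or {}
    out = EdgeExtraction(edges=[])
    seen: set[tuple[str, str, str]] = set()

    def emit(a: str, b: str, rtype: str) -> None:
        if a == b:
            return
        key = (min(a, b), max(a, b), rtype)
        if key not in seen:
            seen.add(key)
            out.edges.append(key)

    for rel in doc.relations:
        out.n_relations += 1
        if rel.type not in GENE_EDGE_RELATION_TYPES:
            out.n_skipped += 1
            continue
        genes1 = _entry_gene_symbols(doc, rel.entry1, id_map)
        genes2 = _entry_gene_symbols(doc, rel.entry2, id_map)
        if not genes1 or not genes2:
            out.n_skipped += 1
            continue
        contributed = False
        for a, b in itertools.product(sorted(genes1), sorted(genes2)):
            if a != b:
                emit(a, b, rel.type)
                contributed = True
        if not contributed:
            out.n_skipped += 1

    if intra_group_edges:
        for group in doc.groups.values():
            members = sorted(_entry_gene_symbols(doc, group.id, id_map))
            for a, b in itertools.combinations(members, 2):
                emit(a, b, "group")

    return out


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping KEGG gene ids to symbols."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"id-map line has fewer than 2 columns: {line!r}")
        mapping[fields[0]] = fields[1]
    return mapping


def write_id_map(mapping: Mapping[str, str], path: str | Path) -> None:
    lines = [f"{k}\t{v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")
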