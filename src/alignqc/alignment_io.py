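"""Alignment parsing, reference resolution and writing.

Two dialects are supported: the Alignment API RDF/XML format
(``Alignment`` / ``map`` / ``Cell`` with ``entity1``, ``entity2``,
``relation``, ``measure``) and a delimited text dialect (by default a
comma-separated three-column table ``entity1,entity2,relation``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from ._rdf import Literal, RDFParseError, URIRef, parse_rdf, xml_escape
from .ontology_io import OntologyDocument

ALIGN_NS = "http://knowledgeweb.semanticweb.org/heterogeneity/alignment"

_ABSOLUTE_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://\S+$|^urn:\S+$")


class Relation(str, Enum):
    EQUIVALENT = "equivalentClass"
    SUBCLASS = "subClassOf"        # entity1 is the subclass
    SUPERCLASS = "superClassOf"    # entity1 is the superclass
    RELATED = "relatedTo"
    UNKNOWN = "unknown"


#: Bijective mapping for the Alignment API relation symbols.
SYMBOL_TO_RELATION = {
    "=": Relation.EQUIVALENT,
    "<": Relation.SUBCLASS,
    ">": Relation.SUPERCLASS,
}
RELATION_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_RELATION.items()}

#: Case-insensitive keyword families for the delimited dialect.
_RELATION_KEYWORDS = {
    "equivalent": Relation.EQUIVALENT,
    "equivalentclass": Relation.EQUIVALENT,
    "equivalence": Relation.EQUIVALENT,
    "equal": Relation.EQUIVALENT,
    "=": Relation.EQUIVALENT,
    "subclass": Relation.SUBCLASS,
    "subclassof": Relation.SUBCLASS,
    "<": Relation.SUBCLASS,
    "superclass": Relation.SUPERCLASS,
    "superclassof": Relation.SUPERCLASS,
    ">": Relation.SUPERCLASS,
    "related": Relation.RELATED,
    "relatedto": Relation.RELATED,
}


class AlignmentParseError(Exception):
    """Fatal alignment parse failure (unreadable, or zero usable rows)."""


class UnresolvedReferencesError(Exception):
    """Raised when writing an alignment that still has unresolved refs."""


class Resolution(str, Enum):
    UNRESOLVED = "unresolved"   # resolve_references not run yet
    RESOLVED = "resolved"
    MISSING = "missing"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class EntityRef:
    """A reference to an ontology class as written in an alignment file."""

    raw: str
    ref_kind: str  # "uri" | "local_name"
    resolution: Resolution = Resolution.UNRESOLVED
    resolved_uri: str = ""
    candidates: tuple[str, ...] = ()
    repaired: str = ""  # cleaned token actually used, when != raw

    @staticmethod
    def from_token(token: str) -> "EntityRef":
        kind = "uri" if _ABSOLUTE_IRI_RE.match(token) else "local_name"
        return EntityRef(raw=token, ref_kind=kind)


@dataclass(frozen=True)
class Correspondence:
    entity1: EntityRef
    entity2: EntityRef
    relation: Relation
    confidence: float | None = None
    row_provenance: str = ""

    def key(self) -> tuple:
        """Identity for deduplication: resolved pair if available."""
        e1 = self.entity1.resolved_uri or self.entity1.raw
        e2 = self.entity2.resolved_uri or self.entity2.raw
        return (e1, e2, self.relation)

    def resolved(self) -> bool:
        return (
            self.entity1.resolution == Resolution.RESOLVED
            and self.entity2.resolution == Resolution.RESOLVED
        )


@dataclass
class Alignment:
    correspondences: list[Correspondence] = field(default_factory=list)
    onto1_ref: str = ""
    onto2_ref: str = ""
    source_format: str = "alignment_api"  # or "delimited"
    source_location: str = ""
    parse_warnings: list[tuple[str, str]] = field(default_factory=list)

    def of_relation(self, *relations: Relation) -> list[Correspondence]:
        return [c for c in self.correspondences if c.relation in relations]


@dataclass
class DelimitedOptions:
    delimiter: str = ","
    column_order: tuple[str, str, str] = ("entity1", "entity2", "relation")
    has_header: str = "auto"  # "auto" | "yes" | "no"
    entity1_is_subclass: bool = True  # flip to read subclass rows converse


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------


def parse_alignment(
    source,
    dialect: str = "auto",
    delimited_options: DelimitedOptions | None = None,
) -> Alignment:
    """Parse an alignment file in either supported dialect.

    Malformed rows/cells are skipped with warnings; a file with zero
    parseable correspondences is fatal.
    """
    path = Path(source)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise AlignmentParseError("cannot read %s: %s" % (source, exc)) from exc
    if dialect == "auto":
        stripped = text.lstrip()
        dialect = (
            "alignment_api"
            if stripped.startswith("<?xml") or stripped.startswith("<")
            else "delimited"
        )
    if dialect == "alignment_api":
        alignment = _parse_alignment_api(path)
    elif dialect == "delimited":
        alignment = _parse_delimited(path, delimited_options or DelimitedOptions())
    else:
        raise ValueError("unknown dialect %r" % dialect)
    alignment.source_location = str(source)
    _deduplicate(alignment)
    if not alignment.correspondences:
        raise AlignmentParseError(
            "no parseable correspondences in %s (%d warnings)"
            % (source, len(alignment.parse_warnings))
        )
    return alignment


def _parse_alignment_api(path: Path) -> Alignment:
    try:
        graph = parse_rdf(path, fmt="rdfxml")
    except RDFParseError as exc:
        raise AlignmentParseError(str(exc)) from exc
    alignment = Alignment(source_format="alignment_api")
    ns = ALIGN_NS + "#"
    alignment.onto1_ref = _onto_ref(graph, ns + "onto1")
    alignment.onto2_ref = _onto_ref(graph, ns + "onto2")
    cells = sorted(set(graph.subjects(URIRef(ns + "entity1")))
                   | set(graph.subjects(URIRef(ns + "entity2"))),
                   key=str)
    for i, cell in enumerate(cells):
        prov = "cell:%d" % (i + 1)
        e1 = graph.value(cell, URIRef(ns + "entity1"))
        e2 = graph.value(cell, URIRef(ns + "entity2"))
        if not isinstance(e1, URIRef) or not isinstance(e2, URIRef):
            alignment.parse_warnings.append(
                (prov, "cell missing entity1/entity2 resource; skipped")
            )
            continue
        rel_node = graph.value(cell, URIRef(ns + "relation"))
        if isinstance(rel_node, Literal) and rel_node.value.strip():
            symbol = rel_node.value.strip()
            relation = SYMBOL_TO_RELATION.get(symbol, Relation.RELATED)
            if relation is Relation.RELATED and symbol not in SYMBOL_TO_RELATION:
                alignment.parse_warnings.append(
                    (prov, "non-standard relation symbol %r read as relatedTo" % symbol)
                )
        else:
            relation = Relation.UNKNOWN
            alignment.parse_warnings.append((prov, "cell without relation symbol"))
        confidence = None
        measure = graph.value(cell, URIRef(ns + "measure"))
        if isinstance(measure, Literal):
            try:
                confidence = float(measure.value)
            except ValueError:
                alignment.parse_warnings.append(
                    (prov, "unparsable measure %r ignored" % measure.value)
                )
        alignment.correspondences.append(
            Correspondence(
                entity1=EntityRef.from_token(str(e1)),
                entity2=EntityRef.from_token(str(e2)),
                relation=relation,
                confidence=confidence,
                row_provenance=prov,
            )
        )
    return alignment


def _onto_ref(graph, prop: str) -> str:
    from ._rdf import BNode

    obj = None
    for o in graph.objects(None, URIRef(prop)):
        obj = o
        break
    if obj is None:
        return ""
    if isinstance(obj, URIRef):
        return str(obj)
    if isinstance(obj, Literal):
        return obj.value.strip()
    if isinstance(obj, BNode):
        # nested Ontology node: rdf:about or a location literal
        for s, p, o in graph.match(obj):
            if str(p).endswith("location") and isinstance(o, Literal):
                return o.value.strip()
        # the bnode subject cannot carry rdf:about; give up
    return ""


def _parse_delimited(path: Path, options: DelimitedOptions) -> Alignment:
    alignment = Alignment(source_format="delimited")
    with open(path, newline="", encoding="utf-8") as handle:
        rows = list(csv.reader(handle, delimiter=options.delimiter))
    if not rows:
        raise AlignmentParseError("empty delimited file %s" % path)
    order = options.column_order
    start = 0
    if options.has_header == "yes" or (
        options.has_header == "auto" and _looks_like_header(rows[0], order)
    ):
        start = 1
    for idx in range(start, len(rows)):
        prov = "row:%d" % (idx + 1)
        row = [cell.strip() for cell in rows[idx]]
        if not any(row):
            continue
        if len(row) < len(order):
            alignment.parse_warnings.append(
                (prov, "expected %d columns, got %d; skipped" % (len(order), len(row)))
            )
            continue
        values = dict(zip(order, row))
        tok1, tok2 = values.get("entity1", ""), values.get("entity2", "")
        if not tok1 or not tok2:
            alignment.parse_warnings.append((prov, "missing entity value; skipped"))
            continue
        rel_token = values.get("relation", "").strip()
        relation = _delimited_relation(rel_token)
        if relation is Relation.RELATED and rel_token.lower() not in _RELATION_KEYWORDS:
            alignment.parse_warnings.append(
                (prov, "unrecognized relation %r read as relatedTo" % rel_token)
            )
        if relation in (Relation.SUBCLASS, Relation.SUPERCLASS) and (
            not options.entity1_is_subclass
        ):
            relation = (
                Relation.SUPERCLASS
                if relation is Relation.SUBCLASS
                else Relation.SUBCLASS
            )
        e1, e2 = EntityRef.from_token(tok1), EntityRef.from_token(tok2)
        if _has_interior_whitespace(tok1) and e1.ref_kind == "local_name":
            alignment.parse_warnings.append((prov, "whitespace inside %r" % tok1))
        if _has_interior_whitespace(tok2) and e2.ref_kind == "local_name":
            alignment.parse_warnings.append((prov, "whitespace inside %r" % tok2))
        alignment.correspondences.append(
            Correspondence(
                entity1=e1, entity2=e2, relation=relation, row_provenance=prov
            )
        )
    return alignment


def _delimited_relation(token: str) -> Relation:
    if not token:
        return Relation.UNKNOWN
    return _RELATION_KEYWORDS.get(token.lower(), Relation.RELATED)


def _looks_like_header(row: list[str], order) -> bool:
    cells = [c.strip().lower() for c in row]
    if any(c in ("entity1", "entity2", "relation", "class1", "class2", "source",
                 "target") for c in cells):
        return True
    # a data row normally carries a recognizable relation token
    try:
        rel_index = list(order).index("relation")
    except ValueError:
        return False
    if rel_index < len(cells):
        token = cells[rel_index]
        return bool(token) and token not in _RELATION_KEYWORDS
    return False


def _has_interior_whitespace(token: str) -> bool:
    return bool(re.search(r"\S\s+\S", token))


def _deduplicate(alignment: Alignment) -> None:
    seen: set = set()
    kept = []
    for corr in alignment.correspondences:
        key = corr.key()
        if key in seen:
            alignment.parse_warnings.append(
                (corr.row_provenance, "duplicate correspondence %r dropped" % (key,))
            )
            continue
        seen.add(key)
        kept.append(corr)
    alignment.correspondences = kept


# --------------------------------------------------------------------------
# Reference resolution
# --------------------------------------------------------------------------


def _clean_token(token: str) -> str:
    return re.sub(r"\s+", "", token).strip("\"'")


def _resolve_ref(
    ref: EntityRef, doc: OntologyDocument, name_index: dict[str, list[str]],
    cleanup: bool,
) -> EntityRef:
    tokens = [(ref.raw, False)]
    if cleanup:
        cleaned = _clean_token(ref.raw)
        if cleaned != ref.raw:
            tokens.append((cleaned, True))
    for token, repaired in tokens:
        if ref.ref_kind == "uri":
            if token in doc.classes:
                return replace(
                    ref,
                    resolution=Resolution.RESOLVED,
                    resolved_uri=token,
                    candidates=(token,),
                    repaired=token if repaired else "",
                )
        else:
            uris = name_index.get(token, [])
            if len(uris) == 1:
                return replace(
                    ref,
                    resolution=Resolution.RESOLVED,
                    resolved_uri=uris[0],
                    candidates=(uris[0],),
                    repaired=token if repaired else "",
                )
            if len(uris) >= 2:
                return replace(
                    ref,
                    resolution=Resolution.AMBIGUOUS,
                    candidates=tuple(uris),
                    repaired=token if repaired else "",
                )
    return replace(ref, resolution=Resolution.MISSING)


def resolve_references(
    alignment: Alignment,
    doc1: OntologyDocument,
    doc2: OntologyDocument,
    cleanup: bool = False,
) -> Alignment:
    """Return a copy with every entity reference given a resolution status.

    URI refs resolve by exact IRI match; local-name refs by local-name
    match over the side's classes (imports included): 0 matches is
    ``missing``, 1 is ``resolved``, 2+ is ``ambiguous``.  ``cleanup``
    additionally tries the whitespace-stripped, quote-trimmed token, and
    logs every repair.
    """
    index1, index2 = doc1.by_local_name(), doc2.by_local_name()
    resolved = Alignment(
        onto1_ref=alignment.onto1_ref,
        onto2_ref=alignment.onto2_ref,
        source_format=alignment.source_format,
        source_location=alignment.source_location,
        parse_warnings=list(alignment.parse_warnings),
    )
    for corr in alignment.correspondences:
        e1 = _resolve_ref(corr.entity1, doc1, index1, cleanup)
        e2 = _resolve_ref(corr.entity2, doc2, index2, cleanup)
        for ref in (e1, e2):
            if ref.repaired:
                resolved.parse_warnings.append(
                    (
                        corr.row_provenance,
                        "repaired %r -> %r" % (ref.raw, ref.repaired),
                    )
                )
        resolved.correspondences.append(replace(corr, entity1=e1, entity2=e2))
    _deduplicate(resolved)
    return resolved


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------


def write_alignment(alignment: Alignment, dest, dialect: str = "alignment_api",
                    allow_unresolved: bool = False) -> None:
    """Write an alignment; refuses when references are still unresolved.

    The round-trip property holds: parsing the written file reproduces
    the same (entity pair, relation) multiset.
    """
    if not allow_unresolved:
        bad = [
            c.row_provenance
            for c in alignment.correspondences
            if not c.resolved()
        ]
        if bad:
            raise UnresolvedReferencesError(
                "unresolved references in: %s" % ", ".join(bad or ["<none>"])
            )
    if dialect == "alignment_api":
        _write_alignment_api(alignment, dest)
    elif dialect == "delimited":
        _write_delimited(alignment, dest)
    else:
        raise ValueError("unknown dialect %r" % dialect)


def _entity_token(ref: EntityRef) -> str:
    return ref.resolved_uri or ref.raw


def _write_alignment_api(alignment: Alignment, dest) -> None:
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<rdf:RDF xmlns="%s#"' % ALIGN_NS,
        '         xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"',
        '         xmlns:xsd="http://www.w3.org/2001/XMLSchema#">',
        "  <Alignment>",
        "    <xml>yes</xml>",
        "    <level>0</level>",
        "    <type>11</type>",
    ]
    for prop, value in (("onto1", alignment.onto1_ref), ("onto2", alignment.onto2_ref)):
        if value:
            lines.append("    <%s>%s</%s>" % (prop, xml_escape(value), prop))
    for corr in alignment.correspondences:
        symbol = RELATION_TO_SYMBOL.get(corr.relation, "?")
        lines.append("    <map>")
        lines.append("      <Cell>")
        lines.append(
            '        <entity1 rdf:resource="%s"/>'
            % xml_escape(_entity_token(corr.entity1))
        )
        lines.append(
            '        <entity2 rdf:resource="%s"/>'
            % xml_escape(_entity_token(corr.entity2))
        )
        if corr.relation is not Relation.UNKNOWN:
            lines.append("        <relation>%s</relation>" % xml_escape(symbol))
        measure = corr.confidence if corr.confidence is not None else 1.0
        lines.append(
            '        <measure rdf:datatype="http://www.w3.org/2001/XMLSchema'
            '#float">%s</measure>' % measure
        )
        lines.append("      </Cell>")
        lines.append("    </map>")
    lines.append("  </Alignment>")
    lines.append("</rdf:RDF>")
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


_RELATION_WORD = {
    Relation.EQUIVALENT: "equivalent",
    Relation.SUBCLASS: "subclass",
    Relation.SUPERCLASS: "superclass",
    Relation.RELATED: "related",
    Relation.UNKNOWN: "",
}


def _write_delimited(alignment: Alignment, dest) -> None:
    with open(dest, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        for corr in alignment.correspondences:
            writer.writerow(
                [
                    _entity_token(corr.entity1),
                    _entity_token(corr.entity2),
                    _RELATION_WORD[corr.relation],
                ]
            )
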