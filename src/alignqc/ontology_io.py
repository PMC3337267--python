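"""Ontology loading, class extraction and taxonomy-closure queries.

Reads RDF/XML and Turtle documents, resolves ``owl:imports`` against the
local filesystem (depth-limited, cycle-safe), and keeps only explicitly
typed named classes.  The taxonomy records asserted ``subClassOf``,
``equivalentClass``, part-of and ``disjointWith`` edges; closure queries
are plain graph reachability — no DL reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from ._rdf import (
    OWL_NS,
    RDF_NS,
    RDFS_NS,
    SKOS_NS,
    BNode,
    Literal,
    RDFParseError,
    TripleGraph,
    URIRef,
    parse_rdf,
    xml_escape,
)

RDF_TYPE = RDF_NS + "type"
OWL_CLASS = OWL_NS + "Class"
RDFS_CLASS = RDFS_NS + "Class"
RDFS_SUBCLASSOF = RDFS_NS + "subClassOf"
RDFS_LABEL = RDFS_NS + "label"
OWL_EQUIVALENT = OWL_NS + "equivalentClass"
OWL_DISJOINT = OWL_NS + "disjointWith"
OWL_IMPORTS = OWL_NS + "imports"
OWL_ONTOLOGY = OWL_NS + "Ontology"
OWL_VERSION_INFO = OWL_NS + "versionInfo"
OWL_DEPRECATED = OWL_NS + "deprecated"
OWL_DEPRECATED_CLASS = OWL_NS + "DeprecatedClass"
OWL_RESTRICTION = OWL_NS + "Restriction"
OWL_ON_PROPERTY = OWL_NS + "onProperty"
OWL_SOME_VALUES = OWL_NS + "someValuesFrom"

#: Label annotation properties considered, in no particular order.
LABEL_PROPERTIES = (
    RDFS_LABEL,
    SKOS_NS + "prefLabel",
    SKOS_NS + "altLabel",
)

#: Local names of object properties read as part-of edges.
PARTOF_LOCAL_NAMES = frozenset({"partOf", "part_of", "BFO_0000050"})

DEFAULT_IMPORT_DEPTH = 10


class OntologyLoadError(Exception):
    """Fatal error: unreadable source or unparsable RDF."""


class UnknownClassError(KeyError):
    """Closure query against a URI that is not a loaded class."""


def local_name(uri: str) -> str:
    """Terminal segment of an IRI: after the last '#', else the last '/'."""
    if "#" in uri:
        return uri.rsplit("#", 1)[1]
    return uri.rstrip("/").rsplit("/", 1)[-1]


@dataclass
class ClassRecord:
    """One named, explicitly typed ontology class."""

    uri: str
    labels: list[tuple[str, str]] = field(default_factory=list)
    explicitly_typed: bool = True
    deprecated: bool = False

    @property
    def local_name(self) -> str:
        return local_name(self.uri)

    def preferred_label(self) -> str:
        """Untagged label first, then English, then document order.

        Falls back to the local name when no labels exist.
        """
        for text, lang in self.labels:
            if lang == "":
                return text
        for text, lang in self.labels:
            if lang == "en" or lang.startswith("en-"):
                return text
        if self.labels:
            return self.labels[0][0]
        return self.local_name

    def label_texts(self, mode: str = "all") -> list[str]:
        """Lexical forms for matching: labels, or local name if none.

        ``mode='primary'`` restricts to the preferred label.
        """
        if mode == "primary" or not self.labels:
            return [self.preferred_label()]
        return [text for text, _ in self.labels]


@dataclass
class TaxonomyGraph:
    """Asserted class-level edges with reachability queries."""

    subclass_edges: set[tuple[str, str]] = field(default_factory=set)
    equivalence_edges: set[tuple[str, str]] = field(default_factory=set)
    partof_edges: set[tuple[str, str]] = field(default_factory=set)
    disjoint_edges: set[tuple[str, str]] = field(default_factory=set)

    def _digraph(self) -> nx.DiGraph:
        g = getattr(self, "_cached_digraph", None)
        if g is None or g.number_of_edges() != len(self.subclass_edges):
            g = nx.DiGraph()
            g.add_edges_from(self.subclass_edges)
            self._cached_digraph = g
        return g

    def ancestors(self, uri: str) -> set[str]:
        """Strict upward closure over subclass edges (cycle-safe)."""
        g = self._digraph()
        if uri not in g:
            return set()
        return nx.descendants(g, uri)  # edges point child -> parent

    def descendants(self, uri: str) -> set[str]:
        """Strict downward closure over subclass edges (cycle-safe)."""
        g = self._digraph()
        if uri not in g:
            return set()
        return nx.ancestors(g, uri)

    def direct_parents(self, uri: str) -> set[str]:
        return {p for c, p in self.subclass_edges if c == uri}

    def equivalent_pair(self, a: str, b: str) -> bool:
        return (a, b) in self.equivalence_edges or (b, a) in self.equivalence_edges

    def disjoint_pair(self, a: str, b: str) -> bool:
        return (a, b) in self.disjoint_edges or (b, a) in self.disjoint_edges

    def partof_pair(self, a: str, b: str) -> bool:
        return (a, b) in self.partof_edges or (b, a) in self.partof_edges


@dataclass
class OntologyDocument:
    """A loaded ontology: named classes plus asserted taxonomy edges."""

    source_location: str = ""
    ontology_iri: str = ""
    version_info: str = ""
    classes: dict[str, ClassRecord] = field(default_factory=dict)
    taxonomy: TaxonomyGraph = field(default_factory=TaxonomyGraph)
    imports_resolved: list[str] = field(default_factory=list)
    imports_failed: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def by_local_name(self) -> dict[str, list[str]]:
        """Map local name -> sorted URIs carrying it (for resolution)."""
        index: dict[str, list[str]] = {}
        for uri in self.classes:
            index.setdefault(local_name(uri), []).append(uri)
        for uris in index.values():
            uris.sort()
        return index


# --------------------------------------------------------------------------
# Loading
# --------------------------------------------------------------------------


def load_ontology(
    source,
    resolve_imports: bool = True,
    import_depth_limit: int = DEFAULT_IMPORT_DEPTH,
) -> OntologyDocument:
    """Load an ontology document (RDF/XML or Turtle) with its imports.

    Unresolvable imports are recorded in ``imports_failed`` and never
    fatal; unreadable or unparsable top-level documents raise
    :class:`OntologyLoadError`.
    """
    doc = OntologyDocument(source_location=str(source))
    seen: set[str] = set()
    _load_into(doc, Path(source), resolve_imports, import_depth_limit, 0, seen, True)
    _drop_edges_outside_classes(doc)
    return doc


def _load_into(
    doc: OntologyDocument,
    path: Path,
    resolve_imports: bool,
    depth_limit: int,
    depth: int,
    seen: set[str],
    top_level: bool,
) -> None:
    key = str(path.resolve())
    if key in seen:
        return
    seen.add(key)
    try:
        graph = parse_rdf(path)
    except (OSError, RDFParseError) as exc:
        if top_level:
            raise OntologyLoadError("cannot load %s: %s" % (path, exc)) from exc
        doc.imports_failed.append(str(path))
        doc.warnings.append("failed import %s: %s" % (path, exc))
        return
    doc.warnings.extend(graph.warnings)
    _extract(doc, graph, top_level)
    if not top_level:
        doc.imports_resolved.append(str(path))
    if not resolve_imports:
        return
    for obj in sorted(set(graph.objects(None, URIRef(OWL_IMPORTS)))):
        if not isinstance(obj, URIRef):
            continue
        if depth + 1 > depth_limit:
            doc.warnings.append(
                "import depth limit %d exceeded at %s" % (depth_limit, obj)
            )
            doc.imports_failed.append(str(obj))
            continue
        target = _import_target(path, str(obj))
        if target is None:
            doc.imports_failed.append(str(obj))
            doc.warnings.append("unresolvable import %s" % obj)
            continue
        _load_into(doc, target, resolve_imports, depth_limit, depth + 1, seen, False)


def _import_target(importer: Path, iri: str) -> Path | None:
    """Map an imports IRI to a local file, if possible."""
    if iri.startswith("file://"):
        from urllib.request import url2pathname
        from urllib.parse import urlparse

        candidate = Path(url2pathname(urlparse(iri).path))
        return candidate if candidate.exists() else None
    if iri.startswith(("http://", "https://")):
        # offline: look for a sibling file named after the IRI tail
        candidate = importer.parent / local_name(iri)
        if candidate.exists():
            return candidate
        for ext in (".owl", ".rdf", ".ttl", ".xml"):
            c = importer.parent / (local_name(iri) + ext)
            if c.exists():
                return c
        return None
    candidate = importer.parent / iri
    return candidate if candidate.exists() else None


def _extract(doc: OntologyDocument, graph: TripleGraph, top_level: bool) -> None:
    typed: dict[str, set[str]] = {}
    for s, _, o in graph.match(None, URIRef(RDF_TYPE)):
        if isinstance(o, URIRef):
            typed.setdefault(str(s), set()).add(str(o))

    # ontology header (first owl:Ontology subject wins, top level only)
    if top_level and not doc.ontology_iri:
        for s in sorted(graph.subjects(URIRef(RDF_TYPE), URIRef(OWL_ONTOLOGY))):
            if isinstance(s, URIRef):
                doc.ontology_iri = str(s)
                version = graph.value(s, URIRef(OWL_VERSION_INFO))
                if isinstance(version, Literal):
                    doc.version_info = version.value
                break

    for s, types in typed.items():
        if OWL_CLASS not in types and RDFS_CLASS not in types:
            continue
        if s.startswith("_:"):
            doc.warnings.append("anonymous class %s skipped" % s)
            continue
        record = doc.classes.setdefault(s, ClassRecord(uri=s))
        if OWL_DEPRECATED_CLASS in types:
            record.deprecated = True
        subject = URIRef(s)
        for prop in LABEL_PROPERTIES:
            for obj in graph.objects(subject, URIRef(prop)):
                if isinstance(obj, Literal):
                    pair = (obj.value, obj.lang)
                    if pair not in record.labels:
                        record.labels.append(pair)
        dep = graph.value(subject, URIRef(OWL_DEPRECATED))
        if isinstance(dep, Literal) and dep.value.strip().lower() == "true":
            record.deprecated = True

    tax = doc.taxonomy
    for s, p, o in graph.triples:
        if isinstance(s, BNode):
            continue
        pred = str(p)
        if pred == RDFS_SUBCLASSOF:
            if isinstance(o, URIRef):
                tax.subclass_edges.add((str(s), str(o)))
            elif isinstance(o, BNode):
                _restriction_edge(doc, graph, str(s), o)
            continue
        if pred == OWL_EQUIVALENT and isinstance(o, URIRef):
            tax.equivalence_edges.add((str(s), str(o)))
        elif pred == OWL_DISJOINT and isinstance(o, URIRef):
            tax.disjoint_edges.add((str(s), str(o)))
        elif local_name(pred) in PARTOF_LOCAL_NAMES and isinstance(o, URIRef):
            tax.partof_edges.add((str(s), str(o)))


def _restriction_edge(doc, graph: TripleGraph, subject: str, bnode: BNode) -> None:
    """Read ``subClassOf [Restriction onProperty part_of someValuesFrom X]``."""
    types = set(map(str, graph.objects(bnode, URIRef(RDF_TYPE))))
    prop = graph.value(bnode, URIRef(OWL_ON_PROPERTY))
    filler = graph.value(bnode, URIRef(OWL_SOME_VALUES))
    if (
        OWL_RESTRICTION in types
        and isinstance(prop, URIRef)
        and isinstance(filler, URIRef)
        and local_name(str(prop)) in PARTOF_LOCAL_NAMES
    ):
        doc.taxonomy.partof_edges.add((subject, str(filler)))
    else:
        doc.warnings.append(
            "anonymous superclass of %s dropped (unsupported restriction)" % subject
        )


def _drop_edges_outside_classes(doc: OntologyDocument) -> None:
    """Enforce that every taxonomy edge endpoint is a loaded class."""
    known = doc.classes.keys()
    tax = doc.taxonomy
    for name in ("subclass_edges", "equivalence_edges", "partof_edges", "disjoint_edges"):
        edges = getattr(tax, name)
        kept = {e for e in edges if e[0] in known and e[1] in known}
        for a, b in sorted(edges - kept):
            missing = a if a not in known else b
            doc.warnings.append(
                "%s edge (%s, %s) dropped: %s is not an explicitly typed class"
                % (name.split("_")[0], a, b, missing)
            )
        setattr(tax, name, kept)


# --------------------------------------------------------------------------
# Closure queries
# --------------------------------------------------------------------------


def ancestors(doc: OntologyDocument, uri: str, reflexive: bool = False) -> set[str]:
    """Transitive superclass closure of ``uri`` (strict unless reflexive)."""
    if uri not in doc.classes:
        raise UnknownClassError(uri)
    result = doc.taxonomy.ancestors(uri)
    result.discard(uri)
    if reflexive:
        result.add(uri)
    return result


def descendants(doc: OntologyDocument, uri: str, reflexive: bool = False) -> set[str]:
    """Transitive subclass closure of ``uri`` (strict unless reflexive)."""
    if uri not in doc.classes:
        raise UnknownClassError(uri)
    result = doc.taxonomy.descendants(uri)
    result.discard(uri)
    if reflexive:
        result.add(uri)
    return result


# --------------------------------------------------------------------------
# Writing (used by the fixture generator; RDF/XML only)
# --------------------------------------------------------------------------


def write_ontology(doc: OntologyDocument, dest) -> None:
    """Serialize a document as deterministic RDF/XML."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"',
        '         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"',
        '         xmlns:owl="http://www.w3.org/2002/07/owl#"',
        '         xmlns:obo="http://purl.obolibrary.org/obo/">',
    ]
    if doc.ontology_iri:
        lines.append('  <owl:Ontology rdf:about="%s">' % xml_escape(doc.ontology_iri))
        if doc.version_info:
            lines.append(
                "    <owl:versionInfo>%s</owl:versionInfo>"
                % xml_escape(doc.version_info)
            )
        lines.append("  </owl:Ontology>")
    tax = doc.taxonomy
    sub = sorted(tax.subclass_edges)
    equiv = sorted(tax.equivalence_edges)
    part = sorted(tax.partof_edges)
    disj = sorted(tax.disjoint_edges)
    for uri in sorted(doc.classes):
        record = doc.classes[uri]
        lines.append('  <owl:Class rdf:about="%s">' % xml_escape(uri))
        for text, lang in record.labels:
            attr = ' xml:lang="%s"' % lang if lang else ""
            lines.append(
                "    <rdfs:label%s>%s</rdfs:label>" % (attr, xml_escape(text))
            )
        for child, parent in sub:
            if child == uri:
                lines.append(
                    '    <rdfs:subClassOf rdf:resource="%s"/>' % xml_escape(parent)
                )
        for a, b in equiv:
            if a == uri:
                lines.append(
                    '    <owl:equivalentClass rdf:resource="%s"/>' % xml_escape(b)
                )
        for a, b in part:
            if a == uri:
                lines.append('    <obo:part_of rdf:resource="%s"/>' % xml_escape(b))
        for a, b in disj:
            if a == uri:
                lines.append(
                    '    <owl:disjointWith rdf:resource="%s"/>' % xml_escape(b)
                )
        if record.deprecated:
            lines.append(
                '    <owl:deprecated rdf:datatype="http://www.w3.org/2001/'
                'XMLSchema#boolean">true</owl:deprecated>'
            )
        lines.append("  </owl:Class>")
    lines.append("</rdf:RDF>")
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")
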