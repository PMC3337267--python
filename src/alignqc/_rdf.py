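"""Minimal RDF triple reader for RDF/XML and Turtle.

Only the constructs needed for class-level ontology extraction are
supported: named and blank nodes, typed node elements, resource- and
literal-valued properties, language tags, datatypes, ``@prefix`` /
``@base``, and anonymous blank nodes.  No reification, no RDF
collections, no ``parseType="Collection"``.  Unsupported constructs are
skipped and reported as warnings, never fatal.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"
SKOS_NS = "http://www.w3.org/2004/02/skos/core#"

RDF_TYPE = RDF_NS + "type"


class URIRef(str):
    """An absolute IRI node."""

    __slots__ = ()


class BNode(str):
    """A blank node label (document-scoped)."""

    __slots__ = ()


@dataclass(frozen=True)
class Literal:
    value: str
    lang: str = ""
    datatype: str = ""

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.value


Node = "URIRef | BNode | Literal"
Triple = "tuple[URIRef | BNode, URIRef, URIRef | BNode | Literal]"


@dataclass
class TripleGraph:
    """A flat bag of triples with simple pattern lookups."""

    triples: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add(self, s, p, o) -> None:
        self.triples.append((s, p, o))

    def match(self, s=None, p=None, o=None) -> Iterator:
        for t in self.triples:
            if s is not None and t[0] != s:
                continue
            if p is not None and t[1] != p:
                continue
            if o is not None and t[2] != o:
                continue
            yield t

    def objects(self, s=None, p=None) -> Iterator:
        for t in self.match(s, p):
            yield t[2]

    def subjects(self, p=None, o=None) -> Iterator:
        for t in self.match(None, p, o):
            yield t[0]

    def value(self, s, p, default=None):
        for o in self.objects(s, p):
            return o
        return default


class RDFParseError(Exception):
    """Raised on syntactically invalid input documents."""


# --------------------------------------------------------------------------
# RDF/XML
# --------------------------------------------------------------------------

_SYNTAX_ATTRS = {
    RDF_NS + "about",
    RDF_NS + "ID",
    RDF_NS + "nodeID",
    RDF_NS + "resource",
    RDF_NS + "datatype",
    RDF_NS + "parseType",
}


def _split_tag(tag: str) -> str:
    """ElementTree qualified tag ``{ns}local`` -> absolute IRI."""
    if tag.startswith("{"):
        ns, local = tag[1:].split("}", 1)
        return ns + local
    return tag


def _attr(elem: ET.Element, name: str):
    return elem.get("{%s}%s" % (RDF_NS, name))


class _RDFXMLParser:
    def __init__(self, base: str):
        self.base = base
        self.graph = TripleGraph()
        self._bnode_counter = 0

    def _new_bnode(self) -> BNode:
        self._bnode_counter += 1
        return BNode("_:b%d" % self._bnode_counter)

    def parse(self, text: str) -> TripleGraph:
        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            raise RDFParseError("invalid RDF/XML: %s" % exc) from exc
        if _split_tag(root.tag) == RDF_NS + "RDF":
            nodes = list(root)
        else:
            nodes = [root]
        for node in nodes:
            self._node_element(node)
        return self.graph

    def _subject_of(self, elem: ET.Element):
        about = _attr(elem, "about")
        if about is not None:
            return URIRef(self._resolve(about))
        rid = _attr(elem, "ID")
        if rid is not None:
            return URIRef(self._resolve("#" + rid))
        node_id = _attr(elem, "nodeID")
        if node_id is not None:
            return BNode("_:" + node_id)
        return self._new_bnode()

    def _resolve(self, ref: str) -> str:
        if re.match(r"^[A-Za-z][A-Za-z0-9+.-]*:", ref):
            return ref
        if ref.startswith("#"):
            return self.base + ref
        if ref == "":
            return self.base
        # relative reference against a hierarchical base
        return self.base.rsplit("/", 1)[0] + "/" + ref

    def _node_element(self, elem: ET.Element, subject=None):
        if subject is None:
            subject = self._subject_of(elem)
        tag = _split_tag(elem.tag)
        if tag != RDF_NS + "Description":
            self.graph.add(subject, URIRef(RDF_TYPE), URIRef(tag))
        # property attributes (literal shorthand)
        for qname, value in elem.attrib.items():
            uri = _split_tag(qname)
            if uri in _SYNTAX_ATTRS or uri.startswith(
                "http://www.w3.org/XML/1998/namespace"
            ):
                continue
            self.graph.add(subject, URIRef(uri), Literal(value))
        for child in elem:
            self._property_element(subject, child)
        return subject

    def _property_element(self, subject, elem: ET.Element) -> None:
        pred = URIRef(_split_tag(elem.tag))
        resource = _attr(elem, "resource")
        if resource is not None:
            self.graph.add(subject, pred, URIRef(self._resolve(resource)))
            return
        node_id = _attr(elem, "nodeID")
        if node_id is not None:
            self.graph.add(subject, pred, BNode("_:" + node_id))
            return
        parse_type = _attr(elem, "parseType")
        if parse_type == "Resource":
            obj = self._new_bnode()
            self.graph.add(subject, pred, obj)
            for child in elem:
                self._property_element(obj, child)
            return
        if parse_type is not None:
            self.graph.warnings.append(
                "unsupported parseType=%r on %s; skipped" % (parse_type, pred)
            )
            return
        children = list(elem)
        if children:
            obj = self._node_element(children[0])
            self.graph.add(subject, pred, obj)
            for extra in children[1:]:
                self.graph.add(subject, pred, self._node_element(extra))
            return
        text = elem.text or ""
        lang = elem.get("{http://www.w3.org/XML/1998/namespace}lang", "")
        datatype = _attr(elem, "datatype") or ""
        self.graph.add(subject, pred, Literal(text, lang=lang, datatype=datatype))


# --------------------------------------------------------------------------
# Turtle
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
      (?P<comment>\#[^\n]*)
    | (?P<iri><[^>]*>)
    | (?P<literal>"(?:[^"\\]|\\.)*")
    | (?P<prefix_decl>@prefix|@base|PREFIX|BASE)
    | (?P<lang>@[A-Za-z][A-Za-z0-9-]*)
    | (?P<dtype>\^\^)
    | (?P<pname>[A-Za-z_][\w-]*)?:(?P<plocal>[\w](?:[\w.-]*[\w-])?)?
    | (?P<kw_a>\ba\b)
    | (?P<bnode_label>_:[\w-]+)
    | (?P<number>[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
    | (?P<punct>[;,.\[\]()])
    | (?P<word>[A-Za-z_][\w-]*)
    | (?P<ws>\s+)
    """,
    re.VERBOSE,
)


class _TurtleParser:
    def __init__(self, base: str):
        self.base = base
        self.prefixes: dict[str, str] = {}
        self.graph = TripleGraph()
        self._bnode_counter = 0
        self.tokens: list[tuple[str, str]] = []
        self.pos = 0

    def _new_bnode(self) -> BNode:
        self._bnode_counter += 1
        return BNode("_:t%d" % self._bnode_counter)

    def _tokenize(self, text: str) -> None:
        i = 0
        while i < len(text):
            m = _TOKEN_RE.match(text, i)
            if m is None:
                raise RDFParseError(
                    "invalid Turtle at offset %d: %r" % (i, text[i : i + 20])
                )
            i = m.end()
            kind = m.lastgroup
            if kind in ("ws", "comment"):
                continue
            if kind in ("plocal", "pname") or (kind is None and ":" in m.group(0)):
                # a prefixed name (possibly the bare default prefix ':')
                self.tokens.append(("pname", m.group(0)))
                continue
            self.tokens.append((kind, m.group(0)))

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, "")

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def _expect_punct(self, char: str) -> None:
        kind, value = self._next()
        if kind != "punct" or value != char:
            raise RDFParseError("expected %r, got %r" % (char, value))

    def parse(self, text: str) -> TripleGraph:
        self._tokenize(text)
        while self._peek()[0] is not None:
            kind, value = self._peek()
            if kind == "prefix_decl":
                self._directive()
            else:
                self._statement()
        return self.graph

    def _directive(self) -> None:
        _, decl = self._next()
        if decl in ("@prefix", "PREFIX"):
            kind, pname = self._next()
            if kind != "pname":
                raise RDFParseError("malformed @prefix declaration")
            prefix = pname.rstrip(":").split(":")[0]
            kind, iri = self._next()
            if kind != "iri":
                raise RDFParseError("malformed @prefix declaration")
            self.prefixes[prefix] = iri[1:-1]
        else:  # @base
            kind, iri = self._next()
            if kind != "iri":
                raise RDFParseError("malformed @base declaration")
            self.base = iri[1:-1]
        if decl.startswith("@"):
            self._expect_punct(".")

    def _statement(self) -> None:
        subject = self._term(as_subject=True)
        self._predicate_object_list(subject)
        self._expect_punct(".")

    def _predicate_object_list(self, subject) -> None:
        while True:
            pred = self._predicate()
            while True:
                obj = self._term()
                self.graph.add(subject, pred, obj)
                if self._peek() == ("punct", ","):
                    self._next()
                    continue
                break
            if self._peek() == ("punct", ";"):
                self._next()
                # allow trailing ';' before '.' or ']'
                if self._peek()[0] == "punct" and self._peek()[1] in ".]":
                    return
                continue
            return

    def _predicate(self):
        kind, value = self._peek()
        if kind == "kw_a" or (kind == "word" and value == "a"):
            self._next()
            return URIRef(RDF_TYPE)
        term = self._term()
        if not isinstance(term, URIRef):
            raise RDFParseError("predicate must be an IRI, got %r" % (term,))
        return term

    def _term(self, as_subject: bool = False):
        kind, value = self._next()
        if kind == "iri":
            return URIRef(self._resolve(value[1:-1]))
        if kind == "pname":
            prefix, _, local = value.partition(":")
            if prefix not in self.prefixes:
                raise RDFParseError("undefined prefix %r" % prefix)
            return URIRef(self.prefixes[prefix] + local)
        if kind == "bnode_label":
            return BNode(value)
        if kind == "punct" and value == "[":
            node = self._new_bnode()
            if self._peek() != ("punct", "]"):
                self._predicate_object_list(node)
            self._expect_punct("]")
            return node
        if as_subject:
            raise RDFParseError("invalid subject token %r" % value)
        if kind == "literal":
            text = _unescape(value[1:-1])
            lang = ""
            datatype = ""
            if self._peek()[0] == "lang":
                lang = self._next()[1][1:]
            elif self._peek()[0] == "dtype":
                self._next()
                dt = self._term()
                datatype = str(dt)
            return Literal(text, lang=lang, datatype=datatype)
        if kind == "number":
            datatype = XSD_NS + ("decimal" if "." in value else "integer")
            return Literal(value, datatype=datatype)
        if kind == "word" and value in ("true", "false"):
            return Literal(value, datatype=XSD_NS + "boolean")
        raise RDFParseError("unexpected token %r" % value)

    def _resolve(self, ref: str) -> str:
        if re.match(r"^[A-Za-z][A-Za-z0-9+.-]*:", ref):
            return ref
        if ref.startswith("#"):
            return self.base + ref
        if ref == "":
            return self.base
        return self.base.rsplit("/", 1)[0] + "/" + ref


def _unescape(text: str) -> str:
    return (
        text.replace("\\n", "\n")
        .replace("\\t", "\t")
        .replace('\\"', '"')
        .replace("\\\\", "\\")
    )


# --------------------------------------------------------------------------
# Entry points
# --------------------------------------------------------------------------


def sniff_format(path: Path, text: str) -> str:
    """Return ``rdfxml`` or ``turtle``, by extension then content."""
    suffix = path.suffix.lower()
    if suffix in (".owl", ".rdf", ".xml"):
        return "rdfxml"
    if suffix in (".ttl", ".n3"):
        return "turtle"
    stripped = text.lstrip()
    if stripped.startswith("<?xml") or stripped.startswith("<rdf:RDF"):
        return "rdfxml"
    if stripped.startswith("<") and ">" in stripped.split("\n", 1)[0]:
        return "rdfxml"
    return "turtle"


def parse_rdf(path, fmt: str = "auto", base: str = "") -> TripleGraph:
    """Parse an RDF document into a :class:`TripleGraph`.

    Raises :class:`RDFParseError` on syntax errors and ``OSError`` when
    the file cannot be read.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if fmt == "auto":
        fmt = sniff_format(path, text)
    if not base:
        base = path.resolve().as_uri()
    if fmt == "rdfxml":
        return _RDFXMLParser(base).parse(text)
    if fmt == "turtle":
        return _TurtleParser(base).parse(text)
    raise ValueError("unknown RDF format %r" % fmt)


def xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )
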