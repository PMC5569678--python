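"""RDF graph handling: loading, term extraction, local descriptions, neighbors.

This module wraps :mod:`rdflib` graphs in a :class:`DatasetGraph` that knows
its dataset name, origin and (optional) named-graph IRI, and provides the
text-extraction primitives the linguistic matcher is built on:

* :func:`local_description` — the bag of lowercase words describing a term,
  drawn from the local name of its IRI and its label/comment annotations;
* :func:`term_neighbors` — the subject / predicate / object neighbor sets of
  a term, used to pull neighboring context into virtual documents;
* :func:`extract_terms` — the classes and properties of a schema, with kind
  inferred from declaration triples or usage position.

Endpoint-backed graphs defer triple access to a minimal SPARQL 1.1 Protocol
client (`SELECT` with JSON results) with an injectable transport.
"""

from __future__ import annotations

import json
import re
import urllib.error
import urllib.parse
import urllib.request
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

import rdflib
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import DC, DCTERMS, FOAF, OWL, RDF, RDFS, SKOS

from .errors import ConfigError, ConnectivityError, FormatError, UnknownDatasetError

# --------------------------------------------------------------------------
# Configurable annotation-property lists (defaults; every consumer accepts
# overrides).  Label-like properties name a term; comment-like ones describe
# it in free text.

LABEL_PROPERTIES: tuple[URIRef, ...] = (
    RDFS.label,
    DC.title,
    DCTERMS.title,
    SKOS.prefLabel,
)

COMMENT_PROPERTIES: tuple[URIRef, ...] = (
    RDFS.comment,
    DC.description,
)

#: Default set of text-bearing properties searched by keyword filters.
TEXT_PROPERTIES: tuple[URIRef, ...] = LABEL_PROPERTIES + COMMENT_PROPERTIES

#: Commonly-used properties accepted as property constraints even when the
#: mediating ontology does not declare them itself (the mediating schema is
#: conventionally extended with widely shared annotation/link properties).
COMMON_PROPERTY_EXTENSION: dict[str, URIRef] = {
    "label": RDFS.label,
    "comment": RDFS.comment,
    "seealso": RDFS.seeAlso,
    "type": RDF.type,
    "sameas": OWL.sameAs,
    "title": DC.title,
    "description": DC.description,
    "identifier": DC.identifier,
    "homepage": FOAF.homepage,
    "page": FOAF.page,
    "depiction": FOAF.depiction,
}

_RDF_FORMATS = {
    "turtle": "turtle",
    "ttl": "turtle",
    "ntriples": "nt",
    "nt": "nt",
    "rdfxml": "xml",
    "xml": "xml",
}

_EXT_FORMATS = {".ttl": "turtle", ".nt": "nt", ".rdf": "xml", ".xml": "xml", ".owl": "xml"}


# --------------------------------------------------------------------------
# Tokenization

_CAMEL_RE = re.compile(r"(?<=[a-z0-9])(?=[A-Z])|(?<=[A-Z])(?=[A-Z][a-z])")
_CHUNK_RE = re.compile(r"[A-Za-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Split ``text`` into lowercase word tokens.

    Splits on any non-alphanumeric character and on camelCase boundaries,
    lowercases, and drops purely numeric tokens (opaque numeric identifiers
    carry no lexical content).
    """
    tokens: list[str] = []
    for chunk in _CHUNK_RE.findall(text):
        for part in _CAMEL_RE.split(chunk):
            part = part.lower()
            if part and not part.isdigit():
                tokens.append(part)
    return tokens


def local_name(iri: str) -> str:
    """The fragment of an IRI after the last ``/``, ``#`` or ``:``."""
    cut = max(iri.rfind("/"), iri.rfind("#"), iri.rfind(":"))
    return iri[cut + 1 :]


# --------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class Term:
    """A class or property of a schema, with its textual descriptions."""

    iri: URIRef
    kind: str  # "class" | "property"
    labels: tuple[str, ...] = ()
    annotations: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("class", "property"):
            raise ValueError(f"bad term kind: {self.kind!r}")


@dataclass
class LocalDescription:
    """A multiset of lowercase word tokens describing a node (LD)."""

    words: Counter = field(default_factory=Counter)

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "LocalDescription":
        return cls(Counter(tokens))

    def __add__(self, other: "LocalDescription") -> "LocalDescription":
        return LocalDescription(self.words + other.words)

    def __bool__(self) -> bool:
        return bool(self.words)

    def __eq__(self, other) -> bool:
        return isinstance(other, LocalDescription) and self.words == other.words

    def total(self) -> int:
        return sum(self.words.values())

    def as_string(self) -> str:
        """Space-joined sorted distinct tokens (the I-Sub comparison form)."""
        return " ".join(sorted(self.words))


class SparqlEndpoint:
    """Minimal SPARQL 1.1 Protocol client (SELECT, JSON results).

    ``transport`` may be overridden with any callable ``(url) -> bytes`` for
    testing; the default uses :mod:`urllib`.
    """

    def __init__(self, url: str, transport: Optional[Callable[[str], bytes]] = None,
                 timeout: float = 30.0):
        self.url = url
        self.timeout = timeout
        self._transport = transport or self._http_get

    def _http_get(self, url: str) -> bytes:
        req = urllib.request.Request(
            url, headers={"Accept": "application/sparql-results+json"}
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return resp.read()
        except (urllib.error.URLError, OSError) as exc:  # pragma: no cover
            raise ConnectivityError(f"endpoint {self.url} unreachable: {exc}") from exc

    def select(self, query: str) -> list[dict]:
        url = self.url + "?" + urllib.parse.urlencode({"query": query})
        try:
            payload = json.loads(self._transport(url))
        except ConnectivityError:
            raise
        except Exception as exc:
            raise ConnectivityError(f"endpoint {self.url} failed: {exc}") from exc
        return payload.get("results", {}).get("bindings", [])


@dataclass
class DatasetGraph:
    """A named RDF dataset: an in-memory graph or an endpoint facade."""

    dataset_name: str
    graph: Graph
    source: str = ""
    graph_iri: Optional[str] = None
    namespace: Optional[str] = None  # entity-IRI prefix, used for x-link resolution
    endpoint: Optional[SparqlEndpoint] = None

    def __len__(self) -> int:
        return len(self.graph)

    def triples(self):
        return self.graph.triples((None, None, None))

    def query(self, sparql: str) -> list[dict]:
        """Run a SELECT query; returns rows as variable-name → node dicts."""
        if self.endpoint is not None:
            rows = []
            for binding in self.endpoint.select(sparql):
                row = {}
                for var, cell in binding.items():
                    if cell["type"] == "uri":
                        row[var] = URIRef(cell["value"])
                    elif cell["type"] == "bnode":
                        row[var] = BNode(cell["value"])
                    else:
                        row[var] = Literal(cell["value"], lang=cell.get("xml:lang"))
                rows.append(row)
            return rows
        result = self.graph.query(sparql)
        names = [str(v) for v in result.vars] if result.vars else []
        return [dict(zip(names, row)) for row in result]

    def describe(self, entity: URIRef) -> list[tuple[URIRef, object]]:
        """All outgoing (predicate, object) pairs of ``entity``."""
        if self.endpoint is not None:
            rows = self.endpoint.select(
                f"SELECT ?p ?o WHERE {{ <{entity}> ?p ?o }}"
            )
            out = []
            for b in rows:
                p = URIRef(b["p"]["value"])
                c = b["o"]
                if c["type"] == "uri":
                    o: object = URIRef(c["value"])
                elif c["type"] == "bnode":
                    o = BNode(c["value"])
                else:
                    o = Literal(c["value"], lang=c.get("xml:lang"))
                out.append((p, o))
            return out
        return [(p, o) for p, o in self.graph.predicate_objects(entity)]


def load_graph(source: str, format: Optional[str] = None, *,
               dataset_name: Optional[str] = None,
               graph_iri: Optional[str] = None,
               namespace: Optional[str] = None,
               transport: Optional[Callable[[str], bytes]] = None) -> DatasetGraph:
    """Load an RDF file (Turtle / N-Triples / RDF-XML) or wrap an endpoint.

    ``format`` is one of ``turtle``, ``ntriples``, ``rdfxml``, ``endpoint``;
    when omitted it is guessed from the file extension.  Parse failures raise
    :class:`FormatError` carrying the parser's line information.
    """
    name = dataset_name or local_name(source.rstrip("/")) or source
    if format == "endpoint" or (format is None and source.startswith(("http://", "https://"))):
        ep = SparqlEndpoint(source, transport=transport)
        return DatasetGraph(name, Graph(), source=source, graph_iri=graph_iri,
                            namespace=namespace, endpoint=ep)
    path = Path(source)
    if not path.exists():
        raise FormatError(f"no such RDF source: {source}")
    if format is None:
        fmt = _EXT_FORMATS.get(path.suffix.lower())
        if fmt is None:
            raise FormatError(f"cannot guess RDF format of {source}")
    else:
        try:
            fmt = _RDF_FORMATS[format]
        except KeyError:
            raise FormatError(f"unsupported RDF format: {format!r}") from None
    g = Graph()
    try:
        g.parse(path.as_posix(), format=fmt)
    except Exception as exc:
        raise FormatError(f"failed to parse {source} as {format or fmt}: {exc}") from exc
    return DatasetGraph(name, g, source=source, graph_iri=graph_iri, namespace=namespace)


def write_canonical_ntriples(dg: DatasetGraph, path: str) -> None:
    """Serialize as N-Triples with sorted lines, for byte-stable comparison."""
    data = dg.graph.serialize(format="nt")
    lines = sorted(line for line in data.splitlines() if line.strip())
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Term extraction

_CLASS_TYPES = (RDFS.Class, OWL.Class)
_PROPERTY_TYPES = (
    RDF.Property,
    OWL.ObjectProperty,
    OWL.DatatypeProperty,
    OWL.AnnotationProperty,
)


def extract_terms(dg: DatasetGraph,
                  label_properties: Iterable[URIRef] = LABEL_PROPERTIES,
                  comment_properties: Iterable[URIRef] = COMMENT_PROPERTIES) -> set[Term]:
    """Collect the class and property terms of a graph.

    An IRI becomes a class when it is explicitly typed as a class, occurs as
    the object of ``rdf:type``, or appears on either side of
    ``rdfs:subClassOf``; it becomes a property when it is used in predicate
    position or explicitly declared as a property.  Explicit declarations win
    when usage is ambiguous.
    """
    g = dg.graph
    class_iris: set[URIRef] = set()
    property_iris: set[URIRef] = set()
    declared_class: set[URIRef] = set()
    declared_prop: set[URIRef] = set()

    for s, p, o in g:
        if isinstance(p, URIRef):
            property_iris.add(p)
        if p == RDF.type and isinstance(o, URIRef):
            class_iris.add(o)
            if o in _CLASS_TYPES and isinstance(s, URIRef):
                declared_class.add(s)
                class_iris.add(s)
            if o in _PROPERTY_TYPES and isinstance(s, URIRef):
                declared_prop.add(s)
                property_iris.add(s)
        if p == RDFS.subClassOf:
            for node in (s, o):
                if isinstance(node, URIRef):
                    class_iris.add(node)

    label_props = tuple(label_properties)
    comment_props = tuple(comment_properties)

    def annotations_of(iri: URIRef) -> tuple[tuple[str, ...], tuple[str, ...]]:
        labels = tuple(
            str(o) for p in label_props for o in g.objects(iri, p)
            if isinstance(o, Literal)
        )
        comments = tuple(
            str(o) for p in comment_props for o in g.objects(iri, p)
            if isinstance(o, Literal)
        )
        return labels, comments

    terms: set[Term] = set()
    for iri in class_iris | property_iris:
        if iri in class_iris and iri in property_iris:
            # ambiguous: prefer an explicit declaration, else predicate usage
            kind = "class" if iri in declared_class and iri not in declared_prop else "property"
        else:
            kind = "class" if iri in class_iris else "property"
        labels, comments = annotations_of(iri)
        terms.add(Term(iri, kind, labels, comments))
    return terms


# --------------------------------------------------------------------------
# Local descriptions and neighbor sets


def local_description(term: Term) -> LocalDescription:
    """Bag of words from the term's IRI local name plus all its annotations."""
    tokens = tokenize(local_name(str(term.iri)))
    for text in term.labels:
        tokens.extend(tokenize(text))
    for text in term.annotations:
        tokens.extend(tokenize(text))
    return LocalDescription.from_tokens(tokens)


def node_description(node, dg: DatasetGraph,
                     label_properties: Iterable[URIRef] = LABEL_PROPERTIES,
                     comment_properties: Iterable[URIRef] = COMMENT_PROPERTIES) -> LocalDescription:
    """LD of an arbitrary node.

    Literals contribute the words of their lexical form; IRIs contribute
    their local name plus annotation values; blank nodes contribute the
    words of their literal property values only.
    """
    if isinstance(node, Literal):
        return LocalDescription.from_tokens(tokenize(str(node)))
    tokens: list[str] = []
    if isinstance(node, URIRef):
        tokens.extend(tokenize(local_name(str(node))))
        for p in tuple(label_properties) + tuple(comment_properties):
            for o in dg.graph.objects(node, p):
                if isinstance(o, Literal):
                    tokens.extend(tokenize(str(o)))
    elif isinstance(node, BNode):
        for _, o in dg.graph.predicate_objects(node):
            if isinstance(o, Literal):
                tokens.extend(tokenize(str(o)))
    return LocalDescription.from_tokens(tokens)


def term_neighbors(term: Term, dg: DatasetGraph) -> tuple[set, set, set]:
    """Subject / predicate / object neighbor sets of a term.

    SN: subjects of triples where the term occurs as predicate or object;
    PN: predicates of triples where the term occurs as subject or object;
    ON: objects of triples where the term occurs as subject or predicate.
    The term itself is excluded from each set; blank nodes and literals are
    retained.
    """
    iri = term.iri
    sn: set = set()
    pn: set = set()
    on: set = set()
    for s, p, o in dg.graph:
        if p == iri or o == iri:
            sn.add(s)
        if s == iri or o == iri:
            pn.add(p)
        if s == iri or p == iri:
            on.add(o)
    sn.discard(iri)
    pn.discard(iri)
    on.discard(iri)
    return sn, pn, on


# --------------------------------------------------------------------------
# Dataset registry


class Registry:
    """Named collection of dataset graphs plus the mediating ontology."""

    def __init__(self, mediating: Optional[DatasetGraph] = None):
        self.mediating = mediating
        self.datasets: dict[str, DatasetGraph] = {}

    def add(self, dg: DatasetGraph) -> None:
        if dg.dataset_name in self.datasets:
            raise UnknownDatasetError(
                f"duplicate dataset name: {dg.dataset_name}")
        self.datasets[dg.dataset_name] = dg

    def get(self, name: str) -> DatasetGraph:
        try:
            return self.datasets[name]
        except KeyError:
            raise UnknownDatasetError(f"unknown dataset: {name}") from None

    def resolve_name(self, name: str) -> str:
        """Case-insensitive dataset-name lookup."""
        for key in self.datasets:
            if key.lower() == name.lower():
                return key
        raise UnknownDatasetError(f"unknown dataset: {name}")

    def names(self) -> list[str]:
        return sorted(self.datasets)

    @classmethod
    def from_config(cls, path: str, transport=None) -> "Registry":
        """Load a registry from a YAML config.

        Schema::

            mediating: {source: path, format: turtle}
            datasets:
              DrugBank: {source: path, format: turtle, graph_iri: ..., namespace: ...}
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        allowed = {"mediating", "datasets"}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown registry keys: {sorted(unknown)}")
        base = Path(path).parent

        def _load(name, entry):
            allowed_entry = {"source", "format", "graph_iri", "namespace"}
            bad = set(entry) - allowed_entry
            if bad:
                raise ConfigError(f"unknown keys in dataset {name!r}: {sorted(bad)}")
            src = entry["source"]
            if not src.startswith(("http://", "https://")):
                src = str((base / src).resolve())
            return load_graph(src, entry.get("format"), dataset_name=name,
                              graph_iri=entry.get("graph_iri"),
                              namespace=entry.get("namespace"),
                              transport=transport)

        med_entry = raw.get("mediating")
        reg = cls(_load("mediating", med_entry) if med_entry else None)
        for name, entry in (raw.get("datasets") or {}).items():
            reg.add(_load(name, entry))
        return reg
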