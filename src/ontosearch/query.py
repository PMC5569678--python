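"""Mapping-based query answering (global-as-view rewriting).

A parsed EASE query is first turned into a *global* query over the
mediating ontology: class constraints are resolved and expanded down the
subclass hierarchy, property constraints are resolved against the mediating
properties (including the common-property extension), plain keywords become
text filters, and dataset constraints restrict the scope.

The global query is then rewritten per dataset through that dataset's
alignment: a class constraint becomes a triple pattern ``⟨?s a c⟩`` and a
property constraint becomes ``⟨?s p ?o⟩``, where ``c``/``p`` are the mapped
local terms; keywords become SPARQL filters and dataset constraints become
named graphs.  One pattern of each present type is combined into one local
conjunctive query, and all combinations over all datasets in scope form the
federated plan (union semantics).  Combinations a dataset cannot express —
a required term with no mapping — are skipped for that dataset rather than
failing the plan.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdflib import Literal, URIRef
from rdflib.namespace import RDFS

from .ease import EaseQuery
from .errors import FederationError, UnknownTermError
from .matching import Alignment
from .rdf_model import (
    COMMON_PROPERTY_EXTENSION,
    TEXT_PROPERTIES,
    DatasetGraph,
    Registry,
    Term,
    extract_terms,
    local_name,
    tokenize,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Domain types


@dataclass
class GlobalQuery:
    """The mediating-ontology form of an EASE query.

    ``class_options`` and ``property_options`` are disjunctive: an entity
    must match at least one option of each non-empty set.  An empty
    ``dataset_scope`` means all registered datasets.
    """

    class_options: set[URIRef] = field(default_factory=set)
    property_options: set[URIRef] = field(default_factory=set)
    keyword_filters: list[str] = field(default_factory=list)
    dataset_scope: set[str] = field(default_factory=set)


@dataclass
class LocalQuery:
    """One conjunctive SPARQL query against one dataset's own vocabulary."""

    dataset_name: str
    class_pattern: Optional[URIRef] = None
    property_pattern: Optional[URIRef] = None
    keywords: list[str] = field(default_factory=list)
    graph_iri: Optional[str] = None


@dataclass
class QueryPlan:
    """The federated set of local queries plus the substitutions used."""

    local_queries: list[LocalQuery] = field(default_factory=list)
    #: per local query: {global term IRI → local term IRI} substitutions
    provenance: list[dict[URIRef, URIRef]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.local_queries


@dataclass
class ResultEntity:
    """One matched entity with its provenance and description."""

    iri: URIRef
    dataset_name: str
    matched_keywords: set[str] = field(default_factory=set)
    #: global (mediating) class options the entity satisfied
    matched_classes: set[URIRef] = field(default_factory=set)
    description: list[tuple[URIRef, object]] = field(default_factory=list)


@dataclass
class ResultSet:
    """Merged, deduplicated results of a federated plan."""

    entities: list[ResultEntity] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def iris(self) -> set[URIRef]:
        return {e.iri for e in self.entities}

    def __len__(self) -> int:
        return len(self.entities)


# --------------------------------------------------------------------------
# Class expansion


def expand_classes(classes: Iterable[URIRef], mediating: DatasetGraph) -> set[URIRef]:
    """Input classes plus the transitive closure of their subclasses.

    Follows ``rdfs:subClassOf`` edges upward from subclasses; cycles
    terminate because the closure is computed as a visited-set walk.
    Unknown classes raise :class:`UnknownTermError`.
    """
    known = {t.iri for t in extract_terms(mediating) if t.kind == "class"}
    g = mediating.graph
    result: set[URIRef] = set()
    for cls in classes:
        if cls not in known:
            raise UnknownTermError(f"unknown mediating class: {cls}")
        stack = [cls]
        while stack:
            current = stack.pop()
            if current in result:
                continue
            result.add(current)
            for sub in g.subjects(RDFS.subClassOf, current):
                if isinstance(sub, URIRef) and sub not in result:
                    stack.append(sub)
    return result


# --------------------------------------------------------------------------
# Name resolution against the mediating ontology


def _display_forms(term: Term) -> set[str]:
    forms = {local_name(str(term.iri)).lower()}
    for label in term.labels:
        squashed = "".join(tokenize(label))
        if squashed:
            forms.add(squashed)
    return forms


def resolve_term(name: str, mediating: DatasetGraph, kind: str) -> URIRef:
    """Case-insensitive match of a typed constraint name to a mediating term.

    Matches the term's IRI local name or any of its labels with delimiters
    removed (users type single ``\\w+`` words, while term names may be
    multi-word).  Property names additionally resolve against the
    common-property extension.
    """
    wanted = name.lower()
    hits = sorted(
        (t.iri for t in extract_terms(mediating)
         if t.kind == kind and wanted in _display_forms(t)),
        key=str,
    )
    if hits:
        return hits[0]
    if kind == "property" and wanted in COMMON_PROPERTY_EXTENSION:
        return COMMON_PROPERTY_EXTENSION[wanted]
    raise UnknownTermError(f"unknown mediating {kind}: {name}")


def build_global_query(query: EaseQuery, mediating: DatasetGraph,
                       registry: Registry) -> GlobalQuery:
    """Resolve and expand an EASE query against the mediating ontology."""
    gq = GlobalQuery(keyword_filters=list(query.plain_keywords))
    if query.class_constraints:
        resolved = {resolve_term(c, mediating, "class") for c in query.class_constraints}
        gq.class_options = expand_classes(resolved, mediating)
    if query.property_constraints:
        gq.property_options = {
            resolve_term(p, mediating, "property") for p in query.property_constraints
        }
    for s in query.dataset_constraints:
        gq.dataset_scope.add(registry.resolve_name(s))
    return gq


# --------------------------------------------------------------------------
# Rewriting


def rewrite_to_local(global_query: GlobalQuery,
                     alignments: dict[str, Alignment],
                     registry: Registry) -> QueryPlan:
    """Substitute global terms by their mapped local terms, per dataset.

    Every (dataset × class option × property option) combination with
    complete mappings yields one :class:`LocalQuery`; a 1-to-many mapping
    fans out into one query per target.  Datasets that cannot express a
    required constraint are skipped with a warning entry.
    """
    plan = QueryPlan()
    scope = sorted(global_query.dataset_scope) or registry.names()
    for ds_name in scope:
        dg = registry.get(ds_name)
        alignment = alignments.get(ds_name, Alignment(ds_name))

        class_subs: list[tuple[Optional[URIRef], Optional[URIRef]]] = [(None, None)]
        if global_query.class_options:
            class_subs = [
                (src, tgt)
                for src in sorted(global_query.class_options, key=str)
                for tgt in alignment.targets_of(src)
            ]
            if not class_subs:
                plan.warnings.append(
                    f"{ds_name}: no mapping for any class option; dataset skipped")
                continue

        prop_subs: list[tuple[Optional[URIRef], Optional[URIRef]]] = [(None, None)]
        if global_query.property_options:
            prop_subs = [
                (src, tgt)
                for src in sorted(global_query.property_options, key=str)
                for tgt in alignment.targets_of(src)
            ]
            if not prop_subs:
                plan.warnings.append(
                    f"{ds_name}: no mapping for any property option; dataset skipped")
                continue

        for c_src, c_tgt in class_subs:
            for p_src, p_tgt in prop_subs:
                lq = LocalQuery(
                    dataset_name=ds_name,
                    class_pattern=c_tgt,
                    property_pattern=p_tgt,
                    keywords=list(global_query.keyword_filters),
                    graph_iri=dg.graph_iri,
                )
                subs: dict[URIRef, URIRef] = {}
                if c_src is not None:
                    subs[c_src] = c_tgt
                if p_src is not None:
                    subs[p_src] = p_tgt
                plan.local_queries.append(lq)
                plan.provenance.append(subs)
    if plan.is_empty():
        plan.warnings.append("empty plan: no dataset can express the query")
        logger.warning("empty query plan")
    return plan


# --------------------------------------------------------------------------
# SPARQL rendering


def _regex_escape(keyword: str) -> str:
    # escape for a SPARQL regex inside a double-quoted string
    return re.escape(keyword).replace("\\", "\\\\").replace('"', '\\"')


def render_sparql(local: LocalQuery, dialect: str = "portable",
                  text_properties: Iterable[URIRef] = TEXT_PROPERTIES) -> str:
    """Serialize a local query as a SPARQL 1.1 SELECT string.

    The keyword filter requires some literal of ``?s`` on one of the
    configured text properties to case-insensitively match at least one
    keyword (OR-combined regex alternatives).  The ``named-graph`` dialect
    wraps the patterns in the dataset's GRAPH clause.
    """
    if dialect not in ("portable", "named-graph"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    patterns: list[str] = []
    if local.class_pattern is not None:
        patterns.append(f"?s a <{local.class_pattern}> .")
    if local.property_pattern is not None:
        patterns.append(f"?s <{local.property_pattern}> ?v .")
    filters: list[str] = []
    if local.keywords:
        patterns.append("?s ?tp ?txt .")
        prop_test = " || ".join(f"?tp = <{p}>" for p in text_properties)
        kw_test = " || ".join(
            f'REGEX(STR(?txt), "{_regex_escape(kw)}", "i")' for kw in local.keywords
        )
        filters.append(f"FILTER(({prop_test}) && ({kw_test}))")
    if not patterns:
        patterns.append("?s ?p ?o .")
    body = "\n    ".join(patterns + filters)
    if dialect == "named-graph" and local.graph_iri:
        body = f"GRAPH <{local.graph_iri}> {{\n    {body}\n  }}"
    return f"SELECT DISTINCT ?s WHERE {{\n    {body}\n}}"


# --------------------------------------------------------------------------
# Execution


def _matched_keywords(description: list[tuple[URIRef, object]],
                      keywords: Iterable[str],
                      text_properties: Iterable[URIRef]) -> set[str]:
    props = set(text_properties)
    texts = [str(o).lower() for p, o in description
             if p in props and isinstance(o, Literal)]
    return {kw for kw in keywords if any(kw.lower() in t for t in texts)}


def _schema_nodes(dg: DatasetGraph) -> set:
    """Schema-level nodes of a graph: declared classes/properties and
    anything used in predicate position.  Query results contain entities;
    terms are presentation-layer objects (facets), not results."""
    from rdflib.namespace import OWL, RDF, RDFS

    if dg.endpoint is not None:
        return set()
    g = dg.graph
    nodes = set(g.subjects(RDF.type, RDFS.Class))
    nodes |= set(g.subjects(RDF.type, OWL.Class))
    nodes |= set(g.subjects(RDF.type, RDF.Property))
    nodes |= set(g.objects(None, RDF.type))
    nodes |= set(g.predicates())
    return nodes


def execute_plan(plan: QueryPlan, registry: Registry,
                 text_properties: Iterable[URIRef] = TEXT_PROPERTIES) -> ResultSet:
    """Run every local query, merge and deduplicate per (entity, dataset).

    Failures are isolated per dataset: partial results are returned with a
    warning, and only a plan whose every dataset failed raises
    :class:`FederationError`.
    """
    results = ResultSet(warnings=list(plan.warnings))
    by_key: dict[tuple[URIRef, str], ResultEntity] = {}
    attempted: set[str] = set()
    failed: dict[str, str] = {}
    schema_cache: dict[str, set] = {}
    for lq, subs in zip(plan.local_queries, plan.provenance):
        attempted.add(lq.dataset_name)
        if lq.dataset_name in failed:
            continue
        try:
            dg = registry.get(lq.dataset_name)
            sparql = render_sparql(lq, "portable", text_properties)
            rows = dg.query(sparql)
        except Exception as exc:
            failed[lq.dataset_name] = str(exc)
            results.warnings.append(f"{lq.dataset_name}: query failed: {exc}")
            continue
        if lq.dataset_name not in schema_cache:
            schema_cache[lq.dataset_name] = _schema_nodes(dg)
        schema = schema_cache[lq.dataset_name]
        global_class = next((src for src, tgt in subs.items()
                             if tgt == lq.class_pattern), None)
        for row in rows:
            s = row.get("s")
            if not isinstance(s, (URIRef,)) or s in schema:
                continue
            key = (s, lq.dataset_name)
            entity = by_key.get(key)
            if entity is None:
                entity = ResultEntity(iri=s, dataset_name=lq.dataset_name,
                                      description=dg.describe(s))
                entity.matched_keywords = _matched_keywords(
                    entity.description, lq.keywords, text_properties)
                by_key[key] = entity
            if global_class is not None:
                entity.matched_classes.add(global_class)
    if attempted and len(failed) == len(attempted):
        raise FederationError(
            "all datasets failed: " + "; ".join(f"{d}: {m}" for d, m in sorted(failed.items())))
    results.entities = [by_key[k] for k in sorted(by_key, key=lambda k: (str(k[0]), k[1]))]
    return results


def answer(query: EaseQuery, registry: Registry,
           alignments: dict[str, Alignment],
           text_properties: Iterable[URIRef] = TEXT_PROPERTIES) -> ResultSet:
    """End-to-end convenience wrapper: global query → plan → execution."""
    gq = build_global_query(query, registry.mediating, registry)
    plan = rewrite_to_local(gq, alignments, registry)
    return execute_plan(plan, registry, text_properties)
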