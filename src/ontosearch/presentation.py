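"""Result presentation: ranking, property grouping, facets, cross-links.

Entities are ranked primarily by how many distinct plain keywords they
match (more is better), with deterministic tie-breaks.  Each entity's
description is partitioned into three display groups — metadata
(RDF(S)/OWL/DC-style annotation namespaces), entity-linking (``x-<name>``
cross-reference properties) and domain-specific (everything else) — each
sorted alphabetically.  The classes and properties of the result entities
are organized into a faceted filter tree whose leaves are dataset terms:
a leaf hangs under the mediating term it is mapped to, or under its
dataset's bucket when unmapped, so dataset-specific vocabulary stays
reachable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdflib import Literal, URIRef
from rdflib.namespace import DC, DCTERMS, FOAF, OWL, RDF, RDFS

from .ease import EaseQuery
from .errors import UnknownFacetError
from .matching import Alignment
from .rdf_model import (
    LABEL_PROPERTIES,
    DatasetGraph,
    Registry,
    local_name,
)

# --------------------------------------------------------------------------
# Grouping configuration

DEFAULT_METADATA_NAMESPACES: tuple[str, ...] = (
    str(RDF), str(RDFS), str(OWL), str(DC), str(DCTERMS), str(FOAF),
)

DEFAULT_XLINK_PATTERN = r"^x-[\w.-]+$"


@dataclass
class GroupingConfig:
    """How description properties are assigned to display groups."""

    metadata_namespaces: tuple[str, ...] = DEFAULT_METADATA_NAMESPACES
    xlink_pattern: str = DEFAULT_XLINK_PATTERN

    def is_metadata(self, prop: URIRef) -> bool:
        return any(str(prop).startswith(ns) for ns in self.metadata_namespaces)

    def is_xlink(self, prop: URIRef) -> bool:
        return re.match(self.xlink_pattern, local_name(str(prop)), re.IGNORECASE) is not None


# --------------------------------------------------------------------------
# Entity cards


@dataclass
class EntityCard:
    """A displayable entity: label, matched keywords, grouped description."""

    iri: URIRef
    dataset_name: str
    display_label: str
    matched_keywords: set[str] = field(default_factory=set)
    matched_classes: set[URIRef] = field(default_factory=set)
    groups: dict[str, list[tuple[URIRef, object]]] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "iri": str(self.iri),
            "dataset": self.dataset_name,
            "label": self.display_label,
            "matched_keywords": sorted(self.matched_keywords),
            "grouped_properties": {
                group: [[str(p), str(v)] for p, v in pairs]
                for group, pairs in self.groups.items()
            },
        }


def group_properties(description: Iterable[tuple[URIRef, object]],
                     config: Optional[GroupingConfig] = None
                     ) -> dict[str, list[tuple[URIRef, object]]]:
    """Partition (property, value) pairs into the three display groups.

    Precedence: entity-linking (x-link pattern) before metadata namespaces,
    so a cross-reference in an annotation namespace still surfaces as a
    link.  Each group is sorted alphabetically by property then value.
    """
    config = config or GroupingConfig()
    groups: dict[str, list[tuple[URIRef, object]]] = {
        "metadata": [], "domain_specific": [], "entity_linking": [],
    }
    for prop, value in description:
        if config.is_xlink(prop):
            groups["entity_linking"].append((prop, value))
        elif config.is_metadata(prop):
            groups["metadata"].append((prop, value))
        else:
            groups["domain_specific"].append((prop, value))
    for pairs in groups.values():
        pairs.sort(key=lambda pv: (str(pv[0]), str(pv[1])))
    return groups


def _display_label(entity) -> str:
    for prop in LABEL_PROPERTIES:
        for p, v in entity.description:
            if p == prop and isinstance(v, Literal):
                return str(v)
    return local_name(str(entity.iri))


def make_card(entity, config: Optional[GroupingConfig] = None) -> EntityCard:
    return EntityCard(
        iri=entity.iri,
        dataset_name=entity.dataset_name,
        display_label=_display_label(entity),
        matched_keywords=set(entity.matched_keywords),
        matched_classes=set(entity.matched_classes),
        groups=group_properties(entity.description, config),
    )


def rank_results(results, query: EaseQuery,
                 config: Optional[GroupingConfig] = None) -> list[EntityCard]:
    """Order entities by relevance; stable and deterministic.

    Sort key: number of distinct plain keywords matched (descending), then
    number of matched class options (descending), then display label, then
    IRI — so results containing more of the query's keywords come first and
    ties resolve alphabetically.
    """
    cards = [make_card(e, config) for e in results.entities]
    cards.sort(key=lambda c: (
        -len(c.matched_keywords),
        -len(c.matched_classes),
        c.display_label,
        str(c.iri),
    ))
    return cards


# --------------------------------------------------------------------------
# Faceted filtering


@dataclass(frozen=True)
class FacetLeaf:
    """A selectable facet: one dataset term (or one dataset bucket)."""

    kind: str                      # "class" | "property" | "dataset"
    term: Optional[URIRef]         # None for dataset facets
    dataset_name: str
    parent: str                    # mediating-term IRI or dataset bucket name
    count: int


@dataclass
class FacetTree:
    """Two facet roots (classes, properties) plus per-dataset counts.

    ``classes`` / ``properties`` map a parent key — the IRI string of a
    mediating term for mapped leaves, or ``dataset:<name>`` for unmapped
    ones — to its leaves.
    """

    classes: dict[str, list[FacetLeaf]] = field(default_factory=dict)
    properties: dict[str, list[FacetLeaf]] = field(default_factory=dict)
    datasets: dict[str, int] = field(default_factory=dict)

    def leaves(self) -> list[FacetLeaf]:
        out = [leaf for group in self.classes.values() for leaf in group]
        out += [leaf for group in self.properties.values() for leaf in group]
        out += [FacetLeaf("dataset", None, name, "datasets", count)
                for name, count in sorted(self.datasets.items())]
        return out

    def to_json(self) -> dict:
        def dump(root):
            return {
                parent: [
                    {"term": str(l.term), "dataset": l.dataset_name, "count": l.count}
                    for l in leaves
                ]
                for parent, leaves in sorted(root.items())
            }
        return {"classes": dump(self.classes), "properties": dump(self.properties),
                "datasets": dict(sorted(self.datasets.items()))}


def _entity_terms(entity) -> tuple[set[URIRef], set[URIRef]]:
    classes = {o for p, o in entity.description
               if p == RDF.type and isinstance(o, URIRef)}
    props = {p for p, _ in entity.description}
    return classes, props


def build_facets(results, alignments: dict[str, Alignment],
                 mediating: Optional[DatasetGraph] = None) -> FacetTree:
    """Extract the classes, properties and datasets of the result entities.

    Each distinct (dataset, term) of the results becomes exactly one leaf
    counting distinct entities; the leaf attaches under a mediating term iff
    an alignment mapping connects them, and under its dataset bucket
    otherwise.
    """
    tree = FacetTree()
    class_counts: dict[tuple[str, URIRef], int] = {}
    prop_counts: dict[tuple[str, URIRef], int] = {}
    for entity in results.entities:
        tree.datasets[entity.dataset_name] = tree.datasets.get(entity.dataset_name, 0) + 1
        classes, props = _entity_terms(entity)
        for cls in classes:
            key = (entity.dataset_name, cls)
            class_counts[key] = class_counts.get(key, 0) + 1
        for prop in props:
            key = (entity.dataset_name, prop)
            prop_counts[key] = prop_counts.get(key, 0) + 1

    def parent_of(ds_name: str, term: URIRef) -> str:
        alignment = alignments.get(ds_name)
        if alignment:
            sources = sorted({str(m.source_term) for m in alignment.mappings
                              if m.target_term == term})
            if sources:
                return sources[0]
        return f"dataset:{ds_name}"

    for (ds_name, term), count in sorted(class_counts.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        parent = parent_of(ds_name, term)
        tree.classes.setdefault(parent, []).append(
            FacetLeaf("class", term, ds_name, parent, count))
    for (ds_name, term), count in sorted(prop_counts.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        parent = parent_of(ds_name, term)
        tree.properties.setdefault(parent, []).append(
            FacetLeaf("property", term, ds_name, parent, count))
    return tree


def apply_facet(results, leaf: FacetLeaf):
    """Refine a result set to the entities carrying the facet; idempotent.

    The leaf must describe terms actually present in ``results`` (a stale
    leaf raises :class:`UnknownFacetError`).
    """
    from .query import ResultSet

    selected = []
    for entity in results.entities:
        classes, props = _entity_terms(entity)
        if leaf.kind == "dataset":
            if entity.dataset_name == leaf.dataset_name:
                selected.append(entity)
        elif leaf.kind == "class":
            if entity.dataset_name == leaf.dataset_name and leaf.term in classes:
                selected.append(entity)
        elif leaf.kind == "property":
            if entity.dataset_name == leaf.dataset_name and leaf.term in props:
                selected.append(entity)
        else:
            raise UnknownFacetError(f"unknown facet kind: {leaf.kind!r}")
    if not selected:
        raise UnknownFacetError(
            f"facet {leaf.kind}={leaf.term or leaf.dataset_name} matches no result entity")
    return ResultSet(entities=selected, warnings=list(results.warnings))


# --------------------------------------------------------------------------
# Cross-dataset links

_XLINK_NAME_RE = re.compile(r"^x-(?P<name>[\w.-]+)$", re.IGNORECASE)


def resolve_xlinks(card: EntityCard, registry: Registry
                   ) -> list[tuple[URIRef, URIRef, str]]:
    """Resolve the entity-linking group into (property, target, dataset).

    The target dataset is inferred from the ``x-<name>`` property local
    name, falling back to the target IRI's namespace against the registry's
    declared entity namespaces; unresolvable targets are reported with
    dataset ``"unknown"``.
    """
    out: list[tuple[URIRef, URIRef, str]] = []
    for prop, value in card.groups.get("entity_linking", []):
        if not isinstance(value, URIRef):
            continue
        dataset = "unknown"
        m = _XLINK_NAME_RE.match(local_name(str(prop)))
        if m:
            try:
                dataset = registry.resolve_name(m.group("name"))
            except Exception:
                dataset = "unknown"
        if dataset == "unknown":
            for name, dg in registry.datasets.items():
                if dg.namespace and str(value).startswith(dg.namespace):
                    dataset = name
                    break
        out.append((prop, value, dataset))
    return out
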