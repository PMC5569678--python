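"""EASE: a constrained keyword query language.

A query is a whitespace-delimited token string.  Besides plain keywords, a
token may carry one of three case-insensitive semantic tags:

====================  ===================  =============
keyword type          pattern              example
====================  ===================  =============
plain text            ``^(?![CPS]:)\\w+``   penicillin
class constraint      ``^C:\\w+``           C:Drug
property constraint   ``^P:\\w+``           P:label
dataset constraint    ``^S:\\w+``           S:DrugBank
====================  ===================  =============

Logical semantics: AND across the four categories, OR within a category, so
``alzheimer C:Phenotype C:Disease`` means
``(alzheimer) AND (C:Phenotype OR C:Disease)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import EmptyQueryError, MalformedTagError
from .rdf_model import DatasetGraph, Registry, extract_terms, local_name, tokenize

TAG_RE = re.compile(r"([CPS]):(\w+)$", re.IGNORECASE)
TAG_PREFIX_RE = re.compile(r"[CPS]:", re.IGNORECASE)

_CATEGORY_BY_TAG = {"C": "class", "P": "property", "S": "dataset"}


@dataclass
class EaseQuery:
    """A parsed EASE query: plain keywords plus three constraint lists."""

    plain_keywords: list[str] = field(default_factory=list)
    class_constraints: list[str] = field(default_factory=list)
    property_constraints: list[str] = field(default_factory=list)
    dataset_constraints: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.plain_keywords or self.class_constraints
                    or self.property_constraints or self.dataset_constraints)

    def render(self) -> str:
        """Round-trippable textual form (category order is normalized)."""
        parts = list(self.plain_keywords)
        parts += [f"C:{c}" for c in self.class_constraints]
        parts += [f"P:{p}" for p in self.property_constraints]
        parts += [f"S:{s}" for s in self.dataset_constraints]
        return " ".join(parts)


def classify_token(token: str) -> tuple[str, str]:
    """Classify one token; returns ``(category, payload)``.

    Categories: ``plain``, ``class``, ``property``, ``dataset``.  A token
    starting with a ``C:``/``P:``/``S:`` tag whose remainder is not a
    ``\\w+`` word raises :class:`MalformedTagError`; any token not starting
    with a tag is a plain keyword (unknown tag letters such as ``X:`` are
    plain text).
    """
    m = TAG_RE.match(token)
    if m:
        return _CATEGORY_BY_TAG[m.group(1).upper()], m.group(2)
    if TAG_PREFIX_RE.match(token):
        raise MalformedTagError(token)
    return "plain", token


def parse_ease(text: str) -> EaseQuery:
    """Parse an EASE query string into its four categories."""
    if not text or not text.strip():
        raise EmptyQueryError("empty query")
    query = EaseQuery()
    buckets = {
        "plain": query.plain_keywords,
        "class": query.class_constraints,
        "property": query.property_constraints,
        "dataset": query.dataset_constraints,
    }
    for token in text.split():
        category, payload = classify_token(token)
        buckets[category].append(payload)
    return query


# --------------------------------------------------------------------------
# Logical form


@dataclass
class LogicalForm:
    """Conjunction of per-category disjunctions.

    ``clauses`` is an ordered list of ``(category, leaves)`` pairs where each
    leaf preserves the original token text (with its tag prefix for
    constraints).
    """

    clauses: list[tuple[str, list[str]]]

    def render(self) -> str:
        return " AND ".join(
            "(" + " OR ".join(leaves) + ")" for _, leaves in self.clauses
        )


def logical_form(query: EaseQuery) -> LogicalForm:
    """The AND-of-ORs semantics of a query."""
    clauses: list[tuple[str, list[str]]] = []
    if query.plain_keywords:
        clauses.append(("plain", list(query.plain_keywords)))
    if query.class_constraints:
        clauses.append(("class", [f"C:{c}" for c in query.class_constraints]))
    if query.property_constraints:
        clauses.append(("property", [f"P:{p}" for p in query.property_constraints]))
    if query.dataset_constraints:
        clauses.append(("dataset", [f"S:{s}" for s in query.dataset_constraints]))
    return LogicalForm(clauses)


# --------------------------------------------------------------------------
# Auto-completion


def _candidate_names(term, fragment: str) -> set[str]:
    """Display names of a term that extend the typed fragment."""
    names = {local_name(str(term.iri))}
    for label in term.labels:
        names.add("".join(tokenize(label)))
    frag = fragment.lower()
    return {n for n in names if n and n.lower().startswith(frag)}


def autocomplete(prefix: str, registry: Registry,
                 ontology: DatasetGraph | None = None) -> list[str]:
    """Candidate completions for a partially typed tagged token.

    ``C:``/``P:`` prefixes complete against mediating-ontology class and
    property names, ``S:`` against registered dataset names.  An unknown tag
    yields an empty list.
    """
    m = re.match(r"([A-Za-z]):(.*)$", prefix.strip())
    if not m:
        return []
    tag, fragment = m.group(1).upper(), m.group(2)
    if tag == "S":
        frag = fragment.lower()
        return sorted(n for n in registry.names() if n.lower().startswith(frag))
    if tag not in ("C", "P"):
        return []
    ontology = ontology or registry.mediating
    if ontology is None:
        return []
    wanted = "class" if tag == "C" else "property"
    out: set[str] = set()
    for term in extract_terms(ontology):
        if term.kind == wanted:
            out |= _candidate_names(term, fragment)
    return sorted(out)
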