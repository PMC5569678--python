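"""Linguistic ontology matching: virtual documents, I-Sub, alignments.

Two matchers score a mediating-ontology term *ts* against a dataset term
*tb*:

* **V-Doc** — cosine similarity of *virtual documents*.  The virtual
  document of a term is its local description LD(t) plus discounted local
  descriptions of its subject, predicate and object neighbors::

      VD(t) = LD(t) + γ_s Σ_{t'∈SN(t)} LD(t')
                    + γ_p Σ_{t'∈PN(t)} LD(t')
                    + γ_o Σ_{t'∈ON(t)} LD(t')

  with weighting factors γ_s, γ_p, γ_o in [0, 1] (0.5 by default).

* **I-Sub** — a string matcher balancing the commonality of two strings
  against their difference, with a Winkler-style common-prefix refinement:
  ``I-Sub = Comm − Diff + Winkler``.  Commonality iteratively removes the
  longest common substring; the difference term discounts the unmatched
  remainders with a difference weight of 0.6; raw values in [−1, 1] are
  clamped to [0, 1].

The combined similarity is ``max(V-Doc, I-Sub)``, and every class–class or
property–property pair at or above the threshold (0.9 by default, chosen
for high precision) becomes an equivalence mapping.  One-to-many mappings
are deliberately retained.  Structural matchers are omitted: the dataset
schemas this targets are too weakly structured to support them.

Local descriptions may be enriched with synonyms from a pluggable provider
(e.g. a thesaurus table) before both matchers run.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from rdflib import URIRef

from .errors import IncompatibleKindError
from .rdf_model import (
    DatasetGraph,
    LocalDescription,
    Term,
    extract_terms,
    local_description,
    node_description,
    term_neighbors,
)

logger = logging.getLogger(__name__)

SynonymProvider = Mapping[str, set]


# --------------------------------------------------------------------------
# Configuration


@dataclass
class MatchConfig:
    """Tunables of the matcher.

    gamma_s / gamma_p / gamma_o weight the subject, predicate and object
    neighbor contributions in virtual documents; ``threshold`` is the
    minimum combined similarity for an equivalence mapping.
    """

    gamma_s: float = 0.5
    gamma_p: float = 0.5
    gamma_o: float = 0.5
    threshold: float = 0.9
    synonym_provider: Optional[SynonymProvider] = None

    def __post_init__(self):
        for name in ("gamma_s", "gamma_p", "gamma_o", "threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True, order=True)
class Mapping_:
    """An equivalence mapping from a mediating term to a dataset term."""

    source_term: URIRef
    target_term: URIRef
    score: float
    relation: str = "equivalence"


# Public alias matching the domain vocabulary.
Mapping = Mapping_


@dataclass
class Alignment:
    """All equivalence mappings found for one dataset."""

    dataset_name: str
    mappings: set[Mapping_] = field(default_factory=set)

    def pairs(self) -> set[tuple[URIRef, URIRef]]:
        return {(m.source_term, m.target_term) for m in self.mappings}

    def sorted_mappings(self) -> list[Mapping_]:
        return sorted(self.mappings, key=lambda m: (str(m.source_term), str(m.target_term)))

    def targets(self) -> set[URIRef]:
        return {m.target_term for m in self.mappings}

    def targets_of(self, source: URIRef) -> list[URIRef]:
        return sorted({m.target_term for m in self.mappings if m.source_term == source},
                      key=str)


# --------------------------------------------------------------------------
# Synonym enrichment


def enrich_with_synonyms(ld: LocalDescription, config: MatchConfig) -> LocalDescription:
    """Add one copy of each synonym of each LD token (idempotent).

    A synonym token already present in the description is not duplicated,
    which makes a second application with the same provider a no-op.
    Without a provider this is the identity.
    """
    provider = config.synonym_provider
    if not provider:
        return ld
    enriched = LocalDescription(ld.words.copy())
    extra: set[str] = set()
    for token in ld.words:
        for syn in provider.get(token, ()):
            if syn not in ld.words:
                extra.add(syn)
    for syn in extra:
        enriched.words[syn] += 1
    return enriched


def load_synonym_table(path: str) -> dict[str, set]:
    """Read a two-column TSV of (token, synonym); symmetric closure applied."""
    table: dict[str, set] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or len(row) < 2:
                continue
            a, b = row[0].strip().lower(), row[1].strip().lower()
            if not a or not b:
                continue
            table.setdefault(a, set()).add(b)
            table.setdefault(b, set()).add(a)
    return table


# --------------------------------------------------------------------------
# Virtual documents (V-Doc)


@dataclass
class VirtualDocument:
    """Weighted bag of words representing a term with neighbor context."""

    weights: dict[str, float] = field(default_factory=dict)

    def add(self, ld: LocalDescription, factor: float) -> None:
        if factor == 0.0:
            return
        for token, count in ld.words.items():
            w = self.weights.get(token, 0.0) + factor * count
            if w != 0.0:
                self.weights[token] = w

    def norm(self) -> float:
        return sum(w * w for w in self.weights.values()) ** 0.5


def build_virtual_document(term: Term, graph: DatasetGraph,
                           config: MatchConfig) -> VirtualDocument:
    """Assemble VD(term) from its LD and its three neighbor sets.

    A node occurring in several neighbor sets contributes once per set, per
    the three independent sums of the definition.
    """
    vd = VirtualDocument()
    vd.add(enrich_with_synonyms(local_description(term), config), 1.0)
    sn, pn, on = term_neighbors(term, graph)
    for nodes, gamma in ((sn, config.gamma_s), (pn, config.gamma_p), (on, config.gamma_o)):
        if gamma == 0.0:
            continue
        for node in nodes:
            vd.add(enrich_with_synonyms(node_description(node, graph), config), gamma)
    return vd


def vdoc_similarity(vd1: VirtualDocument, vd2: VirtualDocument) -> float:
    """Cosine of two virtual documents over the union vocabulary."""
    if not vd1.weights or not vd2.weights:
        return 0.0
    small, large = (vd1.weights, vd2.weights) if len(vd1.weights) <= len(vd2.weights) \
        else (vd2.weights, vd1.weights)
    dot = sum(w * large.get(tok, 0.0) for tok, w in small.items())
    denom = vd1.norm() * vd2.norm()
    if denom == 0.0:
        return 0.0
    return min(1.0, dot / denom)


# --------------------------------------------------------------------------
# I-Sub string similarity

_DIFF_WEIGHT = 0.6        # product-based difference weight
_WINKLER_SCALE = 0.1      # prefix bonus scale
_WINKLER_MAX_PREFIX = 4
_MIN_COMMON_SUBSTRING = 2  # single shared letters carry no lexical signal


def _longest_common_substring(a: str, b: str) -> str:
    """Longest common substring; ties broken by earliest start in a, then b."""
    best = ""
    for i in range(len(a)):
        if len(a) - i <= len(best):
            break
        for j in range(len(b)):
            if len(b) - j <= len(best):
                break
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            if k > len(best):
                best = a[i : i + k]
    return best


def isub_similarity(s1: str, s2: str) -> float:
    """I-Sub similarity of two strings, clamped into [0, 1].

    Strings are compared case-insensitively.  Commonality is measured by
    iteratively removing the maximal common substring; the difference term
    discounts the unmatched fractions of each string; a Winkler-style bonus
    rewards a shared prefix of up to four characters.  Either string empty
    yields 0.
    """
    s1, s2 = s1.lower(), s2.lower()
    if not s1 or not s2:
        return 0.0
    if s1 == s2:
        return 1.0
    # canonical argument order: the greedy substring removal depends on which
    # occurrence is removed first, so symmetry is guaranteed by ordering
    if s2 < s1:
        s1, s2 = s2, s1
    l1, l2 = len(s1), len(s2)
    a, b = s1, s2
    matched = 0
    while True:
        sub = _longest_common_substring(a, b)
        if len(sub) < _MIN_COMMON_SUBSTRING:
            break
        matched += len(sub)
        i = a.find(sub)
        a = a[:i] + a[i + len(sub):]
        j = b.find(sub)
        b = b[:j] + b[j + len(sub):]
    comm = 2.0 * matched / (l1 + l2)
    u1 = (l1 - matched) / l1
    u2 = (l2 - matched) / l2
    p = _DIFF_WEIGHT
    diff = (u1 * u2) / (p + (1.0 - p) * (u1 + u2 - u1 * u2))
    prefix = 0
    for c1, c2 in zip(s1, s2):
        if c1 != c2 or prefix >= _WINKLER_MAX_PREFIX:
            break
        prefix += 1
    winkler = _WINKLER_SCALE * prefix * (1.0 - comm)
    return max(0.0, min(1.0, comm - diff + winkler))


def term_string(term: Term, config: Optional[MatchConfig] = None) -> str:
    """The I-Sub comparison form of a term.

    Labels are preferred over the IRI local name (local names are often
    opaque identifiers); tokens are synonym-enriched, deduplicated and
    sorted so the comparison is order-independent.
    """
    from .rdf_model import tokenize, local_name

    if term.labels:
        tokens = [t for text in term.labels for t in tokenize(text)]
    else:
        tokens = tokenize(local_name(str(term.iri)))
    ld = LocalDescription.from_tokens(tokens)
    if config is not None:
        ld = enrich_with_synonyms(ld, config)
    return ld.as_string()


# --------------------------------------------------------------------------
# Combined similarity and alignment extraction


def combined_similarity(ts: Term, tb: Term,
                        graph_s: DatasetGraph, graph_b: DatasetGraph,
                        config: Optional[MatchConfig] = None) -> float:
    """max(V-Doc, I-Sub) for two terms of the same kind; symmetric."""
    config = config or MatchConfig()
    if ts.kind != tb.kind:
        raise IncompatibleKindError(
            f"cannot compare {ts.kind} {ts.iri} with {tb.kind} {tb.iri}")
    vd_s = build_virtual_document(ts, graph_s, config)
    vd_b = build_virtual_document(tb, graph_b, config)
    vdoc = vdoc_similarity(vd_s, vd_b)
    isub = isub_similarity(term_string(ts, config), term_string(tb, config))
    return max(vdoc, isub)


def match_ontologies(mediating: DatasetGraph, dataset: DatasetGraph,
                     config: Optional[MatchConfig] = None) -> Alignment:
    """Score all same-kind term pairs; keep every pair at/above threshold.

    One-to-many mappings are retained; output ordering is deterministic
    (by source IRI, then target IRI).
    """
    config = config or MatchConfig()
    source_terms = extract_terms(mediating)
    target_terms = extract_terms(dataset)
    alignment = Alignment(dataset.dataset_name)
    if not source_terms or not target_terms:
        logger.warning("empty term set: mediating=%d, %s=%d",
                       len(source_terms), dataset.dataset_name, len(target_terms))
        return alignment

    # Terms with the same IRI on both sides are the same term (shared
    # vocabulary such as annotation properties): they align identically and
    # are not cross-compared against anything else.
    by_iri_source = {t.iri: t for t in source_terms}
    by_iri_target = {t.iri: t for t in target_terms}
    shared = {
        iri for iri in by_iri_source.keys() & by_iri_target.keys()
        if by_iri_source[iri].kind == by_iri_target[iri].kind
    }
    for iri in shared:
        alignment.mappings.add(Mapping_(iri, iri, 1.0))
    source_terms = {t for t in source_terms if t.iri not in shared}
    target_terms = {t for t in target_terms if t.iri not in shared}

    vds_source = {t: build_virtual_document(t, mediating, config) for t in source_terms}
    vds_target = {t: build_virtual_document(t, dataset, config) for t in target_terms}
    strs_source = {t: term_string(t, config) for t in source_terms}
    strs_target = {t: term_string(t, config) for t in target_terms}

    for ts in sorted(source_terms, key=lambda t: str(t.iri)):
        for tb in sorted(target_terms, key=lambda t: str(t.iri)):
            if ts.kind != tb.kind:
                continue
            score = max(
                vdoc_similarity(vds_source[ts], vds_target[tb]),
                isub_similarity(strs_source[ts], strs_target[tb]),
            )
            if score >= config.threshold:
                alignment.mappings.add(Mapping_(ts.iri, tb.iri, round(score, 12)))
    return alignment


# --------------------------------------------------------------------------
# Evaluation helpers


def score_alignment(predicted: Alignment, truth: Alignment) -> tuple[float, float, float]:
    """Set precision / recall / F1 over (source, target) pairs.

    Empty sets follow the usual conventions: precision of an empty
    prediction is 0, recall against an empty truth is 0, and F1 is 0
    whenever precision + recall is 0.
    """
    pred, true = predicted.pairs(), truth.pairs()
    tp = len(pred & true)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(true) if true else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def coverage_rate(alignment: Alignment, dataset: DatasetGraph) -> tuple[float, float]:
    """Fraction of the dataset's class / property terms covered by mappings."""
    targets = alignment.targets()
    classes = [t for t in extract_terms(dataset) if t.kind == "class"]
    props = [t for t in extract_terms(dataset) if t.kind == "property"]
    class_cov = sum(1 for t in classes if t.iri in targets) / len(classes) if classes else 0.0
    prop_cov = sum(1 for t in props if t.iri in targets) / len(props) if props else 0.0
    return class_cov, prop_cov


# --------------------------------------------------------------------------
# Alignment persistence (TSV)

_TSV_HEADER = ["source_iri", "target_iri", "score", "relation"]


def write_alignment(alignment: Alignment, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_HEADER)
        for m in alignment.sorted_mappings():
            writer.writerow([str(m.source_term), str(m.target_term),
                             f"{m.score:.6f}", m.relation])


def read_alignment(path: str, dataset_name: Optional[str] = None) -> Alignment:
    name = dataset_name or Path(path).stem
    alignment = Alignment(name)
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header and header[0] != "source_iri":  # headerless file: treat as row
            fh.seek(0)
            reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if len(row) < 3:
                continue
            relation = row[3] if len(row) > 3 else "equivalence"
            alignment.mappings.add(
                Mapping_(URIRef(row[0]), URIRef(row[1]), float(row[2]), relation))
    return alignment
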