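"""Seeded generator of small heterogeneous RDF fixtures.

The generator emulates a federation of life-science datasets that all
re-express one mediating schema (drugs, diseases, genes …) under their own
vocabulary conventions, the way independently published RDF datasets do:

* a **mediating ontology** with a class hierarchy, labelled classes and
  properties, plus the shared common properties (``rdfs:label``,
  ``dc:title``) declared as part of its property set;
* one graph per **dataset**, whose schema terms are known perturbations of
  the mediating terms — letter-case changes, delimiter swaps
  (camel/hyphen/underscore), synonym substitutions, or an added qualifier
  affix that yields one-to-many correspondences;
* typed, labelled **entities** whose labels embed keywords from a fixed
  pool verbatim, so keyword hits are enumerable by construction;
* ``x-<dataset>`` **cross-link** triples between entities of different
  datasets;
* the **ground-truth alignment** for every dataset and a **homogenized**
  merged graph in which every dataset term is rewritten back to its
  mediating term — the oracle against which federated query answering is
  checked.

Entity IRIs are minted in a per-dataset namespace, so homogenization only
rewrites schema vocabulary and never renames entities.  All output is a
pure function of the spec (including its seed).
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DC, RDF, RDFS

from .errors import FixtureSpecError
from .matching import Alignment, Mapping_
from .query import GlobalQuery
from .rdf_model import (
    TEXT_PROPERTIES,
    DatasetGraph,
    Registry,
    extract_terms,
    tokenize,
    write_canonical_ntriples,
)

logger = logging.getLogger(__name__)

MED_NS = "http://example.org/mediator/vocabulary/"

DEFAULT_CLASSES: tuple[tuple[str, Optional[str]], ...] = (
    ("Entity", None),
    ("Molecule", "Entity"),
    ("Drug", "Molecule"),
    ("Disease", "Entity"),
    ("Phenotype", "Disease"),
    ("RareDisease", "Disease"),
    ("Gene", "Entity"),
    ("Protein", "Entity"),
)

DEFAULT_PROPERTIES: tuple[str, ...] = (
    "treats", "targets", "dosage", "toxicity", "indication", "sideEffect",
)

DEFAULT_SYNONYMS: tuple[tuple[str, str], ...] = (
    ("disease", "disorder"),
    ("drug", "medication"),
    ("gene", "locus"),
    ("protein", "polypeptide"),
    ("phenotype", "trait"),
    ("molecule", "compound"),
    ("treats", "heals"),
    ("toxicity", "poisoning"),
)

DEFAULT_KEYWORDS: tuple[str, ...] = (
    "alzheimer", "tuberculosis", "penicillin", "aspirin", "malaria",
    "warfarin", "insulin", "smallpox", "schizophrenia", "caffeine",
)

DEFAULT_DATASET_NAMES: tuple[str, ...] = ("Alpha", "Beta", "Gamma", "Delta", "Epsilon")

_VALUE_POOL = ("high", "low", "moderate", "severe", "mild")

_AFFIX_PREFIXES = ("Predominantly", "Primary", "Secondary")

VALID_MODES = ("case", "delimiter", "synonym", "affix")


@dataclass
class FixtureSpec:
    """Everything that determines a fixture bundle (seed included)."""

    n_datasets: int = 3
    classes: tuple[tuple[str, Optional[str]], ...] = DEFAULT_CLASSES
    properties: tuple[str, ...] = DEFAULT_PROPERTIES
    n_entities_per_class: int = 3
    perturbation_modes: tuple[str, ...] = ("case", "delimiter", "synonym")
    synonym_table: tuple[tuple[str, str], ...] = DEFAULT_SYNONYMS
    n_xlinks: int = 4
    text_keyword_pool: tuple[str, ...] = DEFAULT_KEYWORDS
    dataset_names: tuple[str, ...] = DEFAULT_DATASET_NAMES
    seed: int = 0

    def validate(self) -> None:
        bad = [m for m in self.perturbation_modes if m not in VALID_MODES]
        if bad:
            raise FixtureSpecError(f"unknown perturbation modes: {bad}")
        if "synonym" in self.perturbation_modes and not self.synonym_table:
            raise FixtureSpecError("synonym mode requires a synonym_table")
        if self.n_datasets > len(self.dataset_names):
            raise FixtureSpecError("not enough dataset names for n_datasets")
        schema_tokens = {t for name, _ in self.classes for t in tokenize(name)}
        schema_tokens |= {t for name in self.properties for t in tokenize(name)}
        schema_tokens |= {t for pair in self.synonym_table for t in pair}
        clash = schema_tokens & set(self.text_keyword_pool)
        if clash:
            raise FixtureSpecError(
                f"keyword pool overlaps schema/synonym tokens: {sorted(clash)}")

    def synonyms(self) -> dict[str, set]:
        table: dict[str, set] = {}
        for a, b in self.synonym_table:
            table.setdefault(a.lower(), set()).add(b.lower())
            table.setdefault(b.lower(), set()).add(a.lower())
        return table


@dataclass
class FixtureBundle:
    """A generated fixture: graphs, ground truth and the oracle graph."""

    spec: FixtureSpec
    mediating_ontology: DatasetGraph
    datasets: list[DatasetGraph]
    truth_alignments: dict[str, Alignment]
    xlink_table: list[tuple[URIRef, URIRef, URIRef, str]]
    homogenized: DatasetGraph

    def registry(self) -> Registry:
        reg = Registry(self.mediating_ontology)
        for dg in self.datasets:
            reg.add(dg)
        return reg

    def dataset_of(self, iri: URIRef) -> Optional[str]:
        for dg in self.datasets:
            if dg.namespace and str(iri).startswith(dg.namespace):
                return dg.dataset_name
        return None


# --------------------------------------------------------------------------
# Name perturbation


def _join_tokens(tokens: list[str], style: str) -> str:
    if style == "camel":
        return "".join(t.capitalize() for t in tokens)
    sep = "-" if style == "hyphen" else "_"
    return sep.join(t.capitalize() for t in tokens)


def perturb_term_name(name: str, mode: str, rng: random.Random,
                      synonyms: Optional[dict[str, set]] = None) -> str:
    """One perturbed variant of a term name; token identity is preserved.

    ``case`` re-cases the tokens (keeping boundaries visible via a hyphen
    join when needed); ``delimiter`` re-joins the tokens with a different
    convention; ``synonym`` substitutes tokens through the table (a token
    absent from the table passes through, logged); ``affix`` prepends a
    qualifier token and pluralizes, emulating narrower sibling classes.
    """
    tokens = tokenize(name)
    if not tokens:
        return name
    if mode == "case":
        transform = rng.choice([str.lower, str.upper, str.capitalize])
        sep = "-" if len(tokens) > 1 else ""
        return sep.join(transform(t) for t in tokens)
    if mode == "delimiter":
        style = rng.choice(["camel", "hyphen", "underscore"])
        return _join_tokens(tokens, style)
    if mode == "synonym":
        table = synonyms or {}
        out = []
        for t in tokens:
            if t in table:
                out.append(sorted(table[t])[0])
            else:
                logger.debug("synonym mode: token %r not in table; unchanged", t)
                out.append(t)
        return _join_tokens(out, "camel")
    if mode == "affix":
        prefix = rng.choice(_AFFIX_PREFIXES)
        return f"{prefix}-{'-'.join(tokens)}s"
    raise FixtureSpecError(f"unknown perturbation mode: {mode!r}")


def _perturb_vocabulary(names: Iterable[str], mode: str, rng: random.Random,
                        synonyms: dict[str, set]) -> dict[str, list[str]]:
    """Map each mediating name to its dataset variant(s), injectively.

    Affix mode keeps the original name and adds an affixed twin (1-to-many);
    other modes produce a single variant.  Collisions between distinct
    mediating names are retried, then rejected.
    """
    out: dict[str, list[str]] = {}
    used: set[str] = set()
    for name in names:
        if mode == "affix":
            variants = [name, perturb_term_name(name, "affix", rng, synonyms)]
        else:
            variants = None
            for _ in range(20):
                cand = perturb_term_name(name, mode, rng, synonyms)
                if cand.lower() not in used or cand.lower() in {v.lower() for v in out.get(name, [])}:
                    variants = [cand]
                    break
            if variants is None:
                raise FixtureSpecError(f"cannot find injective perturbation for {name!r}")
        for v in variants:
            if v.lower() in used:
                raise FixtureSpecError(f"perturbation collision on {v!r}")
            used.add(v.lower())
        out[name] = variants
    return out


# --------------------------------------------------------------------------
# Graph assembly


def _label_of(name: str) -> str:
    return " ".join(tokenize(name))


def _build_mediating(spec: FixtureSpec) -> DatasetGraph:
    g = Graph()
    for name, parent in spec.classes:
        iri = URIRef(MED_NS + name)
        g.add((iri, RDF.type, RDFS.Class))
        g.add((iri, RDFS.label, Literal(_label_of(name))))
        if parent is not None:
            g.add((iri, RDFS.subClassOf, URIRef(MED_NS + parent)))
    for name in spec.properties:
        iri = URIRef(MED_NS + name)
        g.add((iri, RDF.type, RDF.Property))
        g.add((iri, RDFS.label, Literal(_label_of(name))))
    # common-property extension: shared annotation properties declared as
    # first-class mediating properties
    g.add((RDFS.label, RDF.type, RDF.Property))
    g.add((DC.title, RDF.type, RDF.Property))
    return DatasetGraph("mediating", g, namespace=MED_NS)


def _build_dataset(spec: FixtureSpec, name: str, mode: str,
                   rng: random.Random) -> tuple[DatasetGraph, Alignment]:
    vocab_ns = f"http://example.org/{name.lower()}/vocabulary/"
    entity_ns = f"http://example.org/{name.lower()}/resource/"
    synonyms = spec.synonyms()
    class_names = [c for c, _ in spec.classes]
    class_map = _perturb_vocabulary(class_names, mode, rng, synonyms)
    prop_mode = mode if mode != "affix" else "case"
    prop_map = _perturb_vocabulary(spec.properties, prop_mode, rng, synonyms)

    g = Graph()
    alignment = Alignment(name)
    class_iris: dict[str, list[URIRef]] = {}
    for cname, variants in class_map.items():
        iris = []
        for variant in variants:
            iri = URIRef(vocab_ns + variant)
            g.add((iri, RDF.type, RDFS.Class))
            g.add((iri, RDFS.label, Literal(_label_of(variant))))
            alignment.mappings.add(Mapping_(URIRef(MED_NS + cname), iri, 1.0))
            iris.append(iri)
        class_iris[cname] = iris
    prop_iris: dict[str, URIRef] = {}
    for pname, variants in prop_map.items():
        iri = URIRef(vocab_ns + variants[0])
        prop_iris[pname] = iri
        alignment.mappings.add(Mapping_(URIRef(MED_NS + pname), iri, 1.0))
    # shared vocabulary used by every dataset maps to itself
    for shared in (RDF.type, RDFS.label, DC.title, RDFS.Class):
        alignment.mappings.add(Mapping_(shared, shared, 1.0))

    prop_names = list(spec.properties)
    entity_counter = 0
    entities = []
    for ci, cname in enumerate(class_names):
        token = tokenize(cname)[0]
        for j in range(spec.n_entities_per_class):
            iri = URIRef(f"{entity_ns}{token}-{ci:02d}{j:03d}")
            cls = class_iris[cname][entity_counter % len(class_iris[cname])]
            g.add((iri, RDF.type, cls))
            kws = rng.sample(list(spec.text_keyword_pool), rng.randint(1, 2))
            g.add((iri, RDFS.label, Literal(" ".join(kws))))
            g.add((iri, DC.title, Literal(kws[0])))
            pname = prop_names[entity_counter % len(prop_names)]
            g.add((iri, prop_iris[pname], Literal(rng.choice(_VALUE_POOL))))
            if rng.random() < 0.5:
                extra = prop_names[(entity_counter * 3 + 1) % len(prop_names)]
                g.add((iri, prop_iris[extra], Literal(rng.choice(_VALUE_POOL))))
            entities.append(iri)
            entity_counter += 1

    dg = DatasetGraph(name, g, namespace=entity_ns,
                      graph_iri=f"http://example.org/{name.lower()}/graph")
    return dg, alignment


def _add_xlinks(spec: FixtureSpec, datasets: list[DatasetGraph],
                rng: random.Random) -> list[tuple[URIRef, URIRef, URIRef, str]]:
    if len(datasets) < 2:
        return []
    entity_lists = {
        dg.dataset_name: sorted(
            {s for s in dg.graph.subjects(RDF.type, None)
             if str(s).startswith(dg.namespace or "")},
            key=str)
        for dg in datasets
    }
    by_name = {dg.dataset_name: dg for dg in datasets}
    table = []
    names = [dg.dataset_name for dg in datasets]
    for _ in range(spec.n_xlinks):
        src_name, tgt_name = rng.sample(names, 2)
        src = rng.choice(entity_lists[src_name])
        tgt = rng.choice(entity_lists[tgt_name])
        prop = URIRef(
            f"http://example.org/{src_name.lower()}/vocabulary/x-{tgt_name.lower()}")
        by_name[src_name].graph.add((src, prop, tgt))
        table.append((src, prop, tgt, tgt_name))
    return table


# --------------------------------------------------------------------------
# Homogenization (the oracle graph)

_PASSTHROUGH_PREFIXES = (
    str(RDF), str(RDFS), "http://purl.org/dc/",
    "http://www.w3.org/2002/07/owl#", "http://xmlns.com/foaf/",
    "http://www.w3.org/2004/02/skos/",
)


def _is_xlink_iri(iri: URIRef) -> bool:
    from .rdf_model import local_name
    return local_name(str(iri)).lower().startswith("x-")


def homogenize(bundle_or_datasets, truth_alignments=None) -> DatasetGraph:
    """Merge all datasets, rewriting every schema term to its mediating term.

    Shared annotation vocabulary and x-link properties pass through
    unchanged.  Any other dataset schema term without a mapping makes the
    alignment non-total and is reported.
    """
    if isinstance(bundle_or_datasets, FixtureBundle):
        datasets = bundle_or_datasets.datasets
        truth_alignments = bundle_or_datasets.truth_alignments
    else:
        datasets = bundle_or_datasets
        if truth_alignments is None:
            raise FixtureSpecError("homogenize needs truth alignments")

    merged = Graph()
    unmapped: set[str] = set()
    for dg in datasets:
        alignment = truth_alignments.get(dg.dataset_name, Alignment(dg.dataset_name))
        reverse = {m.target_term: m.source_term for m in alignment.mappings}

        def rewrite(node):
            if not isinstance(node, URIRef):
                return node
            if node in reverse:
                return reverse[node]
            s = str(node)
            if any(s.startswith(p) for p in _PASSTHROUGH_PREFIXES) or _is_xlink_iri(node):
                return node
            if dg.namespace and s.startswith(dg.namespace):
                return node  # entity IRIs are already dataset-namespaced
            if s.startswith(f"http://example.org/{dg.dataset_name.lower()}/vocabulary/"):
                unmapped.add(s)
            return node

        for s, p, o in dg.graph:
            merged.add((rewrite(s), rewrite(p), rewrite(o)))
    if unmapped:
        raise FixtureSpecError(
            f"truth alignment not total; unmapped terms: {sorted(unmapped)}")
    return DatasetGraph("homogenized", merged)


# --------------------------------------------------------------------------
# Generation entry point


def generate(spec: Optional[FixtureSpec] = None) -> FixtureBundle:
    """Produce a fully reproducible fixture bundle from a spec."""
    spec = spec or FixtureSpec()
    spec.validate()
    rng = random.Random(spec.seed)
    mediating = _build_mediating(spec)
    datasets: list[DatasetGraph] = []
    truths: dict[str, Alignment] = {}
    for i in range(spec.n_datasets):
        name = spec.dataset_names[i]
        mode = spec.perturbation_modes[i % len(spec.perturbation_modes)]
        dg, truth = _build_dataset(spec, name, mode, rng)
        datasets.append(dg)
        truths[name] = truth
    xlinks = _add_xlinks(spec, datasets, rng)
    bundle = FixtureBundle(
        spec=spec,
        mediating_ontology=mediating,
        datasets=datasets,
        truth_alignments=truths,
        xlink_table=xlinks,
        homogenized=DatasetGraph("homogenized", Graph()),
    )
    bundle.homogenized = homogenize(bundle)
    return bundle


# --------------------------------------------------------------------------
# The homogenized-graph oracle evaluator
#
# Deliberately a brute-force triple scan, independent of the SPARQL
# rewriting/execution path it is used to check.


def _schema_nodes(dg: DatasetGraph) -> set:
    from rdflib.namespace import OWL

    nodes = set(dg.graph.subjects(RDF.type, RDFS.Class))
    nodes |= set(dg.graph.subjects(RDF.type, OWL.Class))
    nodes |= set(dg.graph.subjects(RDF.type, RDF.Property))
    nodes |= set(dg.graph.objects(None, RDF.type))
    nodes |= {p for p in dg.graph.predicates()}
    return nodes


def evaluate_global(gq: GlobalQuery, dg: DatasetGraph,
                    dataset_of=None,
                    text_properties: Iterable[URIRef] = TEXT_PROPERTIES) -> set[URIRef]:
    """Evaluate a global query directly on a single (homogenized) graph.

    An entity matches when it has at least one type among the class options
    (if any), at least one property among the property options (if any),
    some text-property value containing at least one keyword (if any), and
    lies in the dataset scope (if any).  Schema nodes are not entities.
    """
    g = dg.graph
    schema = _schema_nodes(dg)
    text_props = set(text_properties)
    out: set[URIRef] = set()
    for s in set(g.subjects()):
        if not isinstance(s, URIRef) or s in schema:
            continue
        if gq.dataset_scope:
            ds = dataset_of(s) if dataset_of else None
            if ds not in gq.dataset_scope:
                continue
        pos = list(g.predicate_objects(s))
        if gq.class_options:
            types = {o for p, o in pos if p == RDF.type}
            if not (types & gq.class_options):
                continue
        if gq.property_options:
            preds = {p for p, _ in pos}
            if not (preds & gq.property_options):
                continue
        if gq.keyword_filters:
            texts = [str(o).lower() for p, o in pos if p in text_props]
            if not any(kw.lower() in t for kw in gq.keyword_filters for t in texts):
                continue
        out.add(s)
    return out


# --------------------------------------------------------------------------
# Random well-formed EASE queries


def generate_queries(bundle: FixtureBundle, n: int, seed: int = 0) -> list[str]:
    """``n`` random parseable EASE strings over the bundle's vocabulary."""
    rng = random.Random(seed)
    spec = bundle.spec
    class_names = [c for c, _ in spec.classes]
    prop_names = list(spec.properties) + ["label", "title"]
    ds_names = [dg.dataset_name for dg in bundle.datasets]
    pool = list(spec.text_keyword_pool)
    queries: list[str] = []
    for _ in range(n):
        parts: list[str] = []
        use_kw = rng.random() < 0.7
        use_cls = rng.random() < 0.6
        use_prop = rng.random() < 0.4
        if not (use_kw or use_cls or use_prop):
            use_kw = True
        if use_kw:
            parts += rng.sample(pool, rng.randint(1, 2))
        if use_cls:
            parts += [f"C:{c}" for c in rng.sample(class_names, rng.randint(1, 2))]
        if use_prop:
            parts += [f"P:{p}" for p in rng.sample(prop_names, 1)]
        if rng.random() < 0.3:
            parts.append(f"S:{rng.choice(ds_names)}")
        queries.append(" ".join(parts))
    return queries


# --------------------------------------------------------------------------
# On-disk bundle (Turtle files, alignment TSVs, registry, manifest)


def write_bundle(bundle: FixtureBundle, outdir: str) -> None:
    from .matching import write_alignment
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_canonical_ntriples(bundle.mediating_ontology, str(out / "mediating.nt"))
    registry_cfg: dict = {
        "mediating": {"source": "mediating.nt", "format": "ntriples"},
        "datasets": {},
    }
    for dg in bundle.datasets:
        fname = f"{dg.dataset_name.lower()}.nt"
        write_canonical_ntriples(dg, str(out / fname))
        registry_cfg["datasets"][dg.dataset_name] = {
            "source": fname,
            "format": "ntriples",
            "graph_iri": dg.graph_iri,
            "namespace": dg.namespace,
        }
        write_alignment(bundle.truth_alignments[dg.dataset_name],
                        str(out / f"{dg.dataset_name.lower()}.alignment.tsv"))
    write_canonical_ntriples(bundle.homogenized, str(out / "homogenized.nt"))
    with open(out / "synonyms.tsv", "w", encoding="utf-8") as fh:
        for a, b in bundle.spec.synonym_table:
            fh.write(f"{a}\t{b}\n")
    (out / "registry.yml").write_text(
        yaml.safe_dump(registry_cfg, sort_keys=True), encoding="utf-8")
    manifest = {
        "seed": bundle.spec.seed,
        "datasets": [dg.dataset_name for dg in bundle.datasets],
        "n_classes": len(bundle.spec.classes),
        "n_properties": len(bundle.spec.properties),
        "perturbation_modes": list(bundle.spec.perturbation_modes),
        "n_xlinks": len(bundle.xlink_table),
        "xlinks": [[str(s), str(p), str(t), ds] for s, p, t, ds in bundle.xlink_table],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
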