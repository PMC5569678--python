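"""Global query construction, GAV rewriting, SPARQL rendering, execution."""

import pytest
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS
from rdflib.plugins.sparql import prepareQuery

from ontosearch.ease import parse_ease
from ontosearch.errors import FederationError, UnknownDatasetError, UnknownTermError
from ontosearch.fixtures import evaluate_global, generate_queries
from ontosearch.matching import Alignment, Mapping_
from ontosearch.query import (
    GlobalQuery,
    LocalQuery,
    build_global_query,
    execute_plan,
    expand_classes,
    render_sparql,
    rewrite_to_local,
)
from ontosearch.rdf_model import (
    TEXT_PROPERTIES,
    DatasetGraph,
    Registry,
    extract_terms,
)

from oracles import naive_local_query

EX = "http://example.org/ns/"
MED = "http://example.org/mediator/vocabulary/"


def graph_of(*triples, name="g"):
    g = Graph()
    for t in triples:
        g.add(t)
    return DatasetGraph(name, g)


class TestExpandClasses:
    def test_leaf_class_expands_to_itself(self, bundle):
        gene = URIRef(MED + "Gene")
        assert expand_classes({gene}, bundle.mediating_ontology) == {gene}

    def test_transitive_closure_of_chain(self):
        a, b, c = (URIRef(EX + n) for n in "ABC")
        med = graph_of(
            (a, RDF.type, RDFS.Class), (b, RDF.type, RDFS.Class),
            (c, RDF.type, RDFS.Class),
            (b, RDFS.subClassOf, a), (c, RDFS.subClassOf, b))
        assert expand_classes({a}, med) == {a, b, c}
        assert expand_classes({b}, med) == {b, c}

    def test_cycle_terminates_and_returns_both(self):
        a, b = URIRef(EX + "A"), URIRef(EX + "B")
        med = graph_of((a, RDFS.subClassOf, b), (b, RDFS.subClassOf, a))
        assert expand_classes({a}, med) == {a, b}

    def test_unknown_class_raises(self, bundle):
        with pytest.raises(UnknownTermError, match="Nope"):
            expand_classes({URIRef(MED + "Nope")}, bundle.mediating_ontology)


class TestBuildGlobalQuery:
    def test_class_constraints_resolved_and_expanded(self, bundle):
        reg = bundle.registry()
        gq = build_global_query(parse_ease("Alzheimer C:Disease C:Phenotype"),
                                bundle.mediating_ontology, reg)
        assert gq.keyword_filters == ["Alzheimer"]
        assert {URIRef(MED + "Disease"), URIRef(MED + "Phenotype"),
                URIRef(MED + "RareDisease")} <= gq.class_options

    def test_keyword_only_query_has_full_scope(self, bundle):
        gq = build_global_query(parse_ease("penicillin"),
                                bundle.mediating_ontology, bundle.registry())
        assert gq.class_options == set() and gq.property_options == set()
        assert gq.dataset_scope == set()
        assert gq.keyword_filters == ["penicillin"]

    def test_common_property_extension_resolves(self, bundle):
        gq = build_global_query(parse_ease("x P:label"),
                                bundle.mediating_ontology, bundle.registry())
        assert gq.property_options == {RDFS.label}

    def test_constraint_names_match_case_insensitively(self, bundle):
        gq = build_global_query(parse_ease("x C:raredisease"),
                                bundle.mediating_ontology, bundle.registry())
        assert URIRef(MED + "RareDisease") in gq.class_options

    def test_unknown_names_raise(self, bundle):
        reg = bundle.registry()
        with pytest.raises(UnknownTermError):
            build_global_query(parse_ease("x C:Unicorn"),
                               bundle.mediating_ontology, reg)
        with pytest.raises(UnknownDatasetError):
            build_global_query(parse_ease("x S:Nowhere"),
                               bundle.mediating_ontology, reg)


class TestRewrite:
    def test_synonym_dataset_substitutes_disorder_variant(self, bundle_synonym):
        b = bundle_synonym
        reg = b.registry()
        gq = GlobalQuery(class_options={URIRef(MED + "Disease")},
                         keyword_filters=["alzheimer"])
        plan = rewrite_to_local(gq, b.truth_alignments, reg)
        patterns = {str(lq.class_pattern) for lq in plan.local_queries}
        assert patterns == {"http://example.org/orphanetlike/vocabulary/Disorder"}

    def test_one_to_many_mapping_fans_out(self, bundle_affix):
        b = bundle_affix
        gq = GlobalQuery(class_options={URIRef(MED + "Phenotype")})
        plan = rewrite_to_local(gq, b.truth_alignments, b.registry())
        assert len(plan.local_queries) == 2
        assert len({lq.class_pattern for lq in plan.local_queries}) == 2

    def test_plan_size_formula(self, bundle):
        # one LocalQuery per dataset per mapped class option x property option
        b = bundle
        reg = b.registry()
        gq = build_global_query(parse_ease("aspirin C:Disease P:treats"),
                                b.mediating_ontology, reg)
        plan = rewrite_to_local(gq, b.truth_alignments, reg)
        expected = 0
        for name in reg.names():
            alignment = b.truth_alignments[name]
            n_cls = sum(len(alignment.targets_of(c)) for c in gq.class_options)
            n_prp = sum(len(alignment.targets_of(p)) for p in gq.property_options)
            expected += n_cls * max(1, n_prp)
        assert len(plan.local_queries) == expected

    def test_unmappable_dataset_is_skipped_with_warning(self, bundle):
        b = bundle
        reg = b.registry()
        gq = GlobalQuery(class_options={URIRef(MED + "Drug")})
        crippled = dict(b.truth_alignments)
        crippled["Alpha"] = Alignment("Alpha")  # no mappings at all
        plan = rewrite_to_local(gq, crippled, reg)
        assert all(lq.dataset_name != "Alpha" for lq in plan.local_queries)
        assert any("Alpha" in w for w in plan.warnings)

    def test_empty_plan_is_a_warning_not_an_exception(self, bundle):
        reg = bundle.registry()
        gq = GlobalQuery(class_options={URIRef(MED + "Drug")})
        plan = rewrite_to_local(gq, {}, reg)
        assert plan.is_empty()
        assert any("empty plan" in w for w in plan.warnings)

    def test_keyword_only_query_yields_one_filter_query_per_dataset(self, bundle):
        reg = bundle.registry()
        gq = GlobalQuery(keyword_filters=["aspirin"])
        plan = rewrite_to_local(gq, bundle.truth_alignments, reg)
        assert len(plan.local_queries) == len(reg.names())
        assert all(lq.class_pattern is None for lq in plan.local_queries)


class TestRenderSparql:
    def test_rendered_queries_parse_under_sparql_grammar(self, bundle):
        cls = next(t.iri for t in extract_terms(bundle.datasets[0])
                   if t.kind == "class")
        for lq in (
            LocalQuery("Alpha", class_pattern=cls),
            LocalQuery("Alpha", class_pattern=cls, keywords=["aspirin", "x y"]),
            LocalQuery("Alpha", keywords=["aspirin"]),
            LocalQuery("Alpha"),
        ):
            prepareQuery(render_sparql(lq, "portable"))
        named = LocalQuery("Alpha", class_pattern=cls,
                           graph_iri="http://example.org/alpha/graph")
        prepareQuery(render_sparql(named, "named-graph"))
        assert "GRAPH <http://example.org/alpha/graph>" in render_sparql(named, "named-graph")

    def test_two_keywords_become_two_regex_alternatives(self):
        lq = LocalQuery("d", keywords=["aspirin", "warfarin"])
        sparql = render_sparql(lq)
        assert sparql.count("REGEX(") == 2
        assert '"aspirin"' in sparql and '"warfarin"' in sparql

    def test_execution_agrees_with_naive_evaluator(self, bundle):
        dg = bundle.datasets[0]
        classes = sorted((t.iri for t in extract_terms(dg) if t.kind == "class"),
                         key=str)
        props = sorted((t.iri for t in extract_terms(dg) if t.kind == "property"),
                       key=str)
        cases = [
            LocalQuery(dg.dataset_name, class_pattern=classes[0]),
            LocalQuery(dg.dataset_name, property_pattern=props[0]),
            LocalQuery(dg.dataset_name, keywords=["aspirin"]),
            LocalQuery(dg.dataset_name, class_pattern=classes[1],
                       keywords=["penicillin", "malaria"]),
            LocalQuery(dg.dataset_name, class_pattern=classes[2],
                       property_pattern=props[1], keywords=["insulin"]),
        ]
        for lq in cases:
            rows = dg.query(render_sparql(lq, "portable"))
            got = {row["s"] for row in rows}
            assert got == naive_local_query(lq, dg, TEXT_PROPERTIES)


class TestExecutePlan:
    def test_empty_plan_yields_empty_resultset(self, bundle):
        from ontosearch.query import QueryPlan
        rs = execute_plan(QueryPlan(), bundle.registry())
        assert len(rs) == 0

    def test_entities_deduplicated_across_combinations(self, bundle):
        # C:Entity expands over every class; each entity still appears once
        b = bundle
        reg = b.registry()
        gq = build_global_query(parse_ease("C:Entity aspirin"),
                                b.mediating_ontology, reg)
        plan = rewrite_to_local(gq, b.truth_alignments, reg)
        rs = execute_plan(plan, reg)
        keys = [(e.iri, e.dataset_name) for e in rs.entities]
        assert len(keys) == len(set(keys))

    def test_failures_are_isolated_per_dataset(self, bundle):
        b = bundle
        reg = b.registry()

        class Broken(DatasetGraph):
            def query(self, sparql):
                raise RuntimeError("endpoint down")

        reg.datasets["Alpha"] = Broken("Alpha", Graph())
        gq = build_global_query(parse_ease("aspirin"), b.mediating_ontology, reg)
        plan = rewrite_to_local(gq, b.truth_alignments, reg)
        rs = execute_plan(plan, reg)
        assert any("Alpha" in w and "failed" in w for w in rs.warnings)
        assert all(e.dataset_name != "Alpha" for e in rs.entities)
        assert len(rs) > 0  # other datasets still answered

    def test_all_datasets_failing_raises_federation_error(self, bundle):
        class Broken(DatasetGraph):
            def query(self, sparql):
                raise RuntimeError("down")

        reg = Registry(bundle.mediating_ontology)
        for dg in bundle.datasets:
            reg.add(Broken(dg.dataset_name, dg.graph))
        gq = GlobalQuery(keyword_filters=["aspirin"])
        plan = rewrite_to_local(gq, bundle.truth_alignments, reg)
        with pytest.raises(FederationError):
            execute_plan(plan, reg)


class TestFederationSemantics:
    """Soundness/completeness and monotonicity of the federated answers."""

    def _federated(self, bundle, text):
        reg = bundle.registry()
        gq = build_global_query(parse_ease(text), bundle.mediating_ontology, reg)
        plan = rewrite_to_local(gq, bundle.truth_alignments, reg)
        return gq, execute_plan(plan, reg)

    def test_agrees_with_homogenized_oracle(self, bundle):
        for text in generate_queries(bundle, 15, seed=23):
            gq, rs = self._federated(bundle, text)
            want = evaluate_global(gq, bundle.homogenized,
                                   dataset_of=bundle.dataset_of)
            assert rs.iris() == want, text

    def test_scope_restriction_is_monotone(self, bundle):
        _, full = self._federated(bundle, "aspirin C:Disease")
        _, scoped = self._federated(bundle, "aspirin C:Disease S:Alpha")
        assert scoped.iris() <= full.iris()
        assert all(e.dataset_name == "Alpha" for e in scoped.entities)

    def test_results_satisfy_per_category_semantics(self, bundle):
        gq, rs = self._federated(bundle, "aspirin malaria C:Disease P:label")
        for e in rs.entities:
            assert e.matched_keywords  # at least one keyword
            assert e.matched_classes   # at least one class option
            types = {o for p, o in e.description if p == RDF.type}
            assert types  # carries a type mapped from some class option

    def test_subclass_expansion_reaches_subclass_entities(self, bundle):
        # querying the parent class returns entities typed with its
        # subclasses; every pool keyword is given so all such entities match
        keywords = " ".join(bundle.spec.text_keyword_pool)
        gq, rs = self._federated(bundle, f"C:Disease {keywords}")
        assert URIRef(MED + "Phenotype") in gq.class_options
        matched = set().union(*(e.matched_classes for e in rs.entities)) \
            if rs.entities else set()
        assert matched & {URIRef(MED + "Phenotype"), URIRef(MED + "RareDisease")}
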