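# Methods

This note documents the models and procedures `ontosearch` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not demonstrate.

## Setting and architecture

The package targets the mediator (global-as-view) style of data
integration over a federation of RDF datasets. A single *mediating
ontology* provides the vocabulary users query against; each dataset keeps
its own schema. Integration happens in two offline/online stages:

1. **Offline**: every dataset schema is aligned to the mediating ontology
   with linguistic ontology matching, producing a set of equivalence
   mappings (mediating term → dataset term, score).
2. **Online**: a user query is resolved against the mediating ontology,
   expanded over the class hierarchy, rewritten through the alignments
   into per-dataset conjunctive SPARQL queries, executed, and merged.

Because mappings point from global terms to source terms, rewriting is a
direct substitution — no view unfolding or query containment reasoning is
needed. The cost is that a dataset that cannot express a required
constraint (no mapping) simply drops out of the plan for that query; the
faceted presentation layer keeps its dataset-specific vocabulary
reachable instead.

## The EASE query language

A query is a whitespace-delimited token string. Three anchored,
case-insensitive patterns classify tokens: `C:\w+` (class constraint),
`P:\w+` (property constraint), `S:\w+` (dataset constraint); any token not
starting with one of the three tag prefixes is a plain keyword (so `X:foo`
is plain text). A token that starts with a tag prefix but whose remainder
is not a `\w+` word (e.g. a bare `C:`) is rejected with an error naming
the token: silently reinterpreting it as a keyword would hide typos in the
most structured part of the query.

Semantics: conjunction across the four categories, disjunction within
one — `alzheimer C:Phenotype C:Disease` reads
`(alzheimer) AND (C:Phenotype OR C:Disease)`. There are no quoted phrases,
no negation and no nesting; multi-keyword queries are softened by ranking
(entities matching more keywords rank higher) rather than by conjunctive
filtering.

Constraint names are matched against mediating terms case-insensitively,
on the IRI local name or on any label with delimiters removed, because
users type single `\w+` words while term names may be multi-word or
opaque.

## Local descriptions and virtual documents

The matcher is purely linguistic; structural matchers are deliberately
absent because weakly structured dataset schemas (flat class lists, few
axioms) give them nothing to work with.

**Local description.** `LD(t)` is a multiset of lowercase word tokens
drawn from the IRI local name (the fragment after the last `/`, `#` or
`:`, split at camel-case, hyphen and underscore boundaries) plus all
label-like (`rdfs:label`, `dc:title`, `dcterms:title`, `skos:prefLabel`)
and comment-like (`rdfs:comment`, `dc:description`) annotation values;
both lists are configurable. Purely numeric tokens are dropped: many
real vocabularies use opaque numeric local names whose meaning lives
entirely in the labels. For a literal node the LD is its lexical form's
words; for a blank node, the words of its literal property values.

**Virtual document.**

```
VD(t) = LD(t) + γ_s Σ_{t'∈SN(t)} LD(t')
              + γ_p Σ_{t'∈PN(t)} LD(t')
              + γ_o Σ_{t'∈ON(t)} LD(t')
```

SN(t) are subjects of triples in which t occurs as predicate or object,
PN(t) predicates of triples in which t occurs as subject or object, ON(t)
objects of triples in which t occurs as subject or predicate (the term
itself excluded; each neighbor contributes once per set it occurs in,
since the three sums are independent). The weighting factors default to
γ_s = γ_p = γ_o = 0.5. Weights are raw token counts with no IDF or
length normalization: the definition is a weighted sum of bags of words,
and on small schemas determinism and transparency matter more than
retrieval-style weighting. `V-Doc` similarity is the cosine of two
virtual documents over their union vocabulary (0 if either is empty).

## I-Sub string similarity

`I-Sub = Comm − Diff + Winkler`, computed case-insensitively:

- **Comm**: iteratively find and remove the longest common substring of
  the two strings until none of at least 2 characters remains;
  `Comm = 2·(total removed length) / (len1 + len2)`. The 2-character
  floor keeps unrelated short names that share scattered single letters
  (e.g. `treats` / `targets`) from accumulating spurious commonality.
  Identical strings short-circuit to similarity 1.
- **Diff**: with unmatched fractions `u1`, `u2` and difference weight
  `p = 0.6`: `Diff = u1·u2 / (p + (1−p)(u1 + u2 − u1·u2))`.
- **Winkler**: `0.1 · min(4, common prefix length) · (1 − Comm)`.

The raw value lies in [−1, 1] and is clamped to [0, 1] so the max
combination below stays a similarity. Two conventions are fixed for
determinism and symmetry: ties among equally long common substrings are
broken by the earliest occurrence (first string, then second), and the
two strings are put in lexicographic order before the removal loop —
the greedy removal is otherwise order-dependent in edge cases.

I-Sub compares terms on the space-joined, sorted, deduplicated tokens of
their local descriptions, preferring label tokens over the IRI local name
(again because local names may be opaque identifiers). Sorting and
deduplication make the comparison order-independent, so perturbations
that preserve the token set (case or delimiter changes) score exactly 1.

## Synonym enrichment

A synonym provider (any mapping token → synonym tokens; shipped as a
two-column TSV with symmetric closure applied on load) enriches local
descriptions before both matchers: each LD token found in the provider
adds one copy of each synonym not already present, which makes enrichment
idempotent. With a symmetric provider, a vocabulary obtained by synonym
substitution enriches to the same token set as its source, so such pairs
score 1 under I-Sub — this is what lifts recall on synonym-divergent
vocabularies (e.g. *Disease* vs *Disorder*) that no string matcher can
recover lexically.

## Alignment extraction

All class–class and property–property pairs between the two term sets are
scored with `Sim = max(V-Doc, I-Sub)`; every pair at or above the
threshold becomes an equivalence mapping. The default threshold of 0.9 is
chosen for precision: in a search setting a wrong mapping silently
returns wrong entities, while a missed mapping only loses one dataset's
contribution, which faceted filtering partially recovers. One-to-many
mappings are retained deliberately — a mediating class may legitimately
correspond to several disjoint dataset classes — so no stable-marriage or
best-match filtering is applied.

Terms whose IRI occurs in both graphs (shared annotation vocabulary such
as `rdf:type` or `rdfs:label`) are aligned identically with score 1 and
excluded from cross-pairing: they are literally the same term, and
cross-comparing ubiquitous co-extensive predicates produces spurious
V-Doc mappings because their subject-neighbor bags nearly coincide.

Known limitation: with a synonym provider enabled, hierarchically related
names sharing an enriched token (e.g. *Disease* vs *Rare-Disease*, both
enriched with *disorder*) can cross the 0.9 threshold. The provider
should therefore be enabled for vocabularies suspected of synonym
divergence rather than unconditionally.

Evaluation helpers compute set precision / recall / F1 of an alignment
against a reference (over (source, target) pairs, with the usual
empty-set conventions) and the coverage rate — the fraction of a
dataset's class (resp. property) terms that are the target of some
mapping.

## Query answering

`build_global_query` resolves class constraints in the mediating ontology
and expands them with the transitive closure of `rdfs:subClassOf`
(visited-set walk, so cycles terminate); property constraints resolve
against mediating properties including a configurable common-property
extension (`label`, `title`, `sameAs`, …) for the shared annotation
vocabulary every dataset uses. Expansion happens on the global side,
before mapping — the global-as-view direction — not in dataset
vocabularies.

`rewrite_to_local` substitutes, per dataset, each class option by each of
its mapped targets and each property option likewise; one pattern of each
present type combines into one local query (`⟨?s a c⟩`, `⟨?s p ?v⟩`, a
keyword filter), and the cross product over options forms the plan. The
keyword filter requires some literal of the entity on a configurable list
of text-bearing properties (the label-like plus comment-like lists by
default) to case-insensitively contain at least one keyword, rendered as
OR-combined `REGEX` alternatives; it is applied inside each local query
rather than post-hoc. Rendered queries are standard SPARQL 1.1 `SELECT
DISTINCT`; a named-graph dialect wraps the patterns in the dataset's
`GRAPH` clause for endpoint deployments.

`execute_plan` runs each local query (in-memory via rdflib, or against a
SPARQL 1.1 Protocol endpoint), fetches each entity's outgoing description
triples, deduplicates per (entity, dataset) and records which keywords
and which global class options each entity matched. Failures are isolated
per dataset — partial results plus a warning — and only a plan whose
every dataset fails raises an error. Results are defined as *entities*:
schema-level nodes (declared classes and properties, objects of
`rdf:type`, anything used as a predicate) are excluded, mirroring the
distinction between terms and entities.

**Correctness property.** The intended semantics is that federated
answering is equivalent to querying a single graph in which every dataset
is rewritten into the mediating vocabulary. The fixture generator
materializes exactly that graph (see below), and the test suite checks
set equality of the two answers for randomly generated queries.

## Presentation

Entity cards are ranked by (1) number of distinct plain keywords matched,
descending; ties broken by (2) number of matched class options, then (3)
display label, then (4) IRI — keys 2–4 are this package's choice purely
for determinism. Descriptions are partitioned into three groups:
entity-linking (property local name matching `x-<name>`, the
cross-reference convention; configurable regex), metadata (property
namespace in RDF/RDFS/OWL/DC/DCTERMS/FOAF; configurable), and
domain-specific (everything else); x-link detection takes precedence so a
cross-reference in an annotation namespace still surfaces as a link.
Groups sort alphabetically by property then value.

The facet tree has two roots (classes, properties). Each distinct
(dataset, term) among result entities becomes one leaf counting distinct
entities; a leaf hangs under the mediating term an alignment maps it to,
otherwise under its dataset bucket, so unmapped dataset-specific
vocabulary remains usable as a filter. Facet counts are computed on the
unranked result set. Applying a leaf filters to entities carrying that
class / property / dataset and is idempotent; a leaf describing nothing
in the results is rejected as stale. `x-<name>` link values resolve to a
target dataset by property name against the registry, falling back to
the target IRI's namespace; unresolvable targets are reported with
dataset `unknown`.

## Synthetic fixtures

The generator emulates the heterogeneity the engine exists to bridge, at
toy scale. Defaults (every value overridable in `FixtureSpec`):

- **Schema**: 8 classes in a small is-a hierarchy (Entity ← {Molecule ←
  Drug, Disease ← {Phenotype, RareDisease}, Gene, Protein}) and 6
  domain properties (treats, targets, dosage, toxicity, indication,
  sideEffect) — the drug / disease / gene entity model typical of
  life-science federations, with multi-token names so delimiter and
  affix perturbations have something to act on.
- **Datasets**: 3, cycling through perturbation modes case → delimiter →
  synonym. *case* re-cases name tokens, *delimiter* re-joins them
  (camel / hyphen / underscore), *synonym* substitutes tokens through the
  table (disease↔disorder, drug↔medication, …), *affix* adds a qualifier
  prefix and plural (`Phenotype` → `Predominantly-phenotypes`-style) and
  keeps the base name too, yielding one-to-many truth mappings. All modes
  preserve token identity, and perturbation is checked to be injective
  per dataset. Shared annotation vocabulary (`rdf:type`, `rdfs:label`,
  `dc:title`, `rdfs:Class`) is used verbatim by every dataset — as real
  federations do — and appears in the ground truth as identity mappings.
- **Entities**: 3 per class per dataset, labelled with 1–2 keywords from
  a 10-word pool embedded verbatim (so keyword hits are enumerable); the
  pool is validated to be disjoint from all schema and synonym tokens so
  keyword filters and schema matching cannot interfere. Each entity
  carries at least one domain-property triple, and each property is used
  in every dataset. Entity IRIs live in per-dataset namespaces from the
  start.
- **Cross-links**: 4 `x-<target>` triples between entities of different
  datasets, recorded in a ground-truth link table.
- **Homogenized oracle graph**: the union of all datasets with every
  schema term rewritten to its mediating term via the truth alignments
  (x-links and shared vocabulary pass through; an unmapped term is an
  error). Because entity IRIs are already namespaced, homogenization
  never renames entities, which makes federated-vs-homogenized answers
  directly comparable as IRI sets.

Everything is a pure function of the spec, seed included; the on-disk
form (canonical sorted N-Triples, TSVs, YAML registry, JSON manifest) is
byte-reproducible.

What passing on fixtures does **not** show: the fixtures are tiny and
lexically clean, entity labels contain keywords verbatim, and the
perturbations are exactly the families the matcher was designed around.
Real vocabularies contain abbreviations, compound jargon and
polysemy that no string matcher resolves; real datasets have millions of
entities where raw-count virtual documents and brute-force pair scoring
would need blocking and endpoint-side filtering. The fixtures validate
the *machinery* (formulas, rewriting, semantics preservation,
presentation invariants), not retrieval quality on real data.

## Numerical and degenerate-input conventions

- All similarities are clamped into [0, 1]; cosine of an empty document
  is 0; I-Sub of an empty string is 0.
- Matching, rewriting and serialization orders are deterministic (sorted
  by IRI) so alignment TSVs and query plans are reproducible.
- An empty term set yields an empty alignment with a warning; an
  inexpressible query yields an empty plan with a warning, not an error;
  a dataset failing at execution yields partial results with a warning.
- Precision of an empty prediction, recall against an empty reference,
  and F1 at zero precision+recall are all reported as 0.

## Problem sizes

The test suite and the acceptance script use the generator defaults
(3 datasets × 8 classes × 3 entities, 100 generated queries for the
semantics-preservation check, 10 seeds for the synonym-recall average,
200 random documents / 50 random string pairs for the operator oracles) —
sizes at which every check is exhaustive and the whole pipeline runs in
seconds on one core.
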