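# ontosearch

Ontology-mediated keyword search over heterogeneous RDF datasets.

Life-science Linked Data federations republish many independently curated
databases as RDF, each under its own vocabulary: one source types diseases
as `Disease`, another as `Disorder`; one writes `Small-molecule`, another
`SmallMolecule`. Writing SPARQL against such a federation requires knowing
every schema. `ontosearch` implements the alternative a mediator
architecture offers: users pose simple constrained keyword queries against
a single *mediating ontology*, and the engine rewrites them — through
automatically computed schema alignments — into per-dataset SPARQL queries
whose union answers the original question (global-as-view integration).

The package is a library plus a CLI, fully testable offline on generated
fixtures that emulate this heterogeneity.

## What it implements

**EASE query language.** Whitespace-delimited tokens; besides plain
keywords, three case-insensitive semantic tags constrain the search:
`C:<class>`, `P:<property>`, `S:<dataset>` (patterns `^C:\w+` etc.;
anything not starting with a tag is plain text). Semantics are AND across
categories, OR within: `alzheimer C:Phenotype C:Disease` means
`(alzheimer) AND (C:Phenotype OR C:Disease)`.

**Linguistic ontology matching.** Two matchers score a mediating term
*t_s* against a dataset term *t_b*:

- *V-Doc*: cosine similarity of virtual documents,
  `V-Doc(t_s, t_b) = VD(t_s)·VD(t_b) / (|VD(t_s)||VD(t_b)|)` with
  `VD(t) = LD(t) + γ_s Σ_{t'∈SN(t)} LD(t') + γ_p Σ_{t'∈PN(t)} LD(t') +
  γ_o Σ_{t'∈ON(t)} LD(t')`, where LD is the bag of words from a term's
  IRI local name and annotations, SN/PN/ON are its subject / predicate /
  object neighbors, and γ = 0.5 by default.
- *I-Sub*: a string matcher `Comm − Diff + Winkler` balancing the common
  substrings of two names against their unmatched remainders, with a
  common-prefix bonus; clamped into [0, 1].

The combined score is `Sim(t_s, t_b) = max(V-Doc, I-Sub)`; every
class–class or property–property pair scoring ≥ 0.9 becomes an equivalence
mapping (one-to-many mappings kept). Local descriptions can be enriched
with synonyms from a pluggable provider (TSV table) before matching.

**Mapping-based query answering.** Class constraints are resolved in the
mediating ontology and expanded down `rdfs:subClassOf`; each class option
becomes a triple pattern `⟨?s a c⟩` and each property option `⟨?s p ?o⟩`
with `c`, `p` substituted through the dataset's alignment; keywords become
SPARQL text filters and dataset constraints named-graph scopes. All
combinations across datasets form the federated plan; per-dataset failures
are isolated.

**Result presentation.** Entities are ranked by distinct keywords matched;
descriptions are split into metadata / domain-specific / entity-linking
groups; result classes and properties build a faceted filter tree (mapped
terms hang under their mediating term, unmapped ones under their dataset);
`x-<dataset>` cross-references resolve to their target datasets.

**Synthetic fixtures.** A seeded generator emits a mediating ontology,
datasets whose vocabularies are known perturbations of it (case, delimiter,
synonym, affix), ground-truth alignments, cross-links, and a *homogenized*
merged graph used as the oracle for query-answering correctness.

## Worked example

```bash
# 1. generate a 3-dataset fixture federation (case / delimiter / synonym
#    perturbed vocabularies)
ontosearch generate-fixtures --out demo --seed 11

# 2. align one dataset schema to the mediating ontology
ontosearch match --mediating demo/mediating.nt --dataset demo/alpha.nt \
    --dataset-name Alpha -o demo/alpha.pred.tsv
# -> 18 mappings -> demo/alpha.pred.tsv

ontosearch evaluate-alignment --predicted demo/alpha.pred.tsv \
    --truth demo/alpha.alignment.tsv
# -> precision=1.0000 recall=1.0000 f1=1.0000

# 3. search the federation
ontosearch search "aspirin C:Disease" --registry demo/registry.yml \
    --alignments demo
```

The search prints the logical form and the ranked entities, e.g.:

```
(aspirin) AND (C:Disease)
Alpha   aspirin                 aspirin http://example.org/alpha/resource/disease-03001
Gamma   tuberculosis aspirin    aspirin http://example.org/gamma/resource/disease-03001
```

Each line is dataset, display label, the keywords matched, and the entity
IRI: the `C:Disease` constraint was expanded over the subclass hierarchy
(`Phenotype`, `RareDisease`) and rewritten per dataset — on Alpha into the
case-variant `DISEASE`/`Rare-Disease` classes, on Gamma into the synonym
variant `Disorder` — and only entities whose labels contain "aspirin" are
returned. `--json` adds the grouped descriptions and the facet tree;
`--facet dataset=Alpha` or `--facet class=<iri>` refine the results.

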