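# scb-kit

Semantic annotation, reasoning, querying and graph mining for systems
chemical biology data.

## The problem

Chemogenomics and systems chemical biology questions — *what are the targets
of this drug? which small-molecule agonists of this receptor weigh under
500 Da? which targets are shared by the drugs that cause this side effect?* —
cut across many heterogeneous databases: compound hubs, drug registries,
binding-assay collections, expression resources, side-effect and disease
catalogs.  Stitched together as raw RDF, these sources keep their own
identifiers and column vocabularies, so every integrative SPARQL query must
name each database and its private schema explicitly.

`scb-kit` is a toolkit for doing this integration *semantically*:

1. **Ontology schema** (`scb.ontology_schema`) — a class/property vocabulary
   for the domain: nine primary classes (`SmallMolecule`, `Drug`, `Protein`,
   `BioAssay`, `Disease`, `SideEffect`, `Literature`, `Pathway`,
   `Interaction`), five `Interaction` subclasses, and a 61-class
   chemogenomic interaction hierarchy split into *chemical-regulates-protein*
   and *protein-regulates-chemical* branches (receptor agonist/antagonist
   activity, activation, inhibition, expression regulation, covalent
   modification, metabolism, transport, ...).  Utility classes carry
   chemical structures, physical properties, bioassay outcomes
   (measurement, relation, value, unit) and cross-reference provenance.
2. **Entity resolution** (`scb.entity_resolution`) — each entity kind is
   unified to one primary identifier namespace (PubChem CID, DrugBank ID,
   UniProt entry name, UMLS ID, Disease Ontology ID) with deterministic URI
   minting, offline InChI→CID lookup, surrogate CIDs for compounds unknown
   to the hub, and token-set matching of free-text disease terms.
3. **Annotation** (`scb.annotation`) — source tables + a column→term mapping
   become one RDF graph in which interactions are first-class nodes with
   participants, assay evidence, publication references, and a
   `UnificationXref` naming the source row each assertion came from.
4. **Reasoning** (`scb.reasoning`) — forward-chaining materialization of
   subclass, subproperty, inverse, transitive and domain/range entailments,
   so a query over `ChemicalProteinInteraction` finds instances asserted
   only at leaf classes.
5. **Queries** (`scb.semantic_query`) — SPARQL execution over the
   materialized graph plus the integrative patterns as templates and
   functions: `drug_targets`, `interaction_evidence`, `ligands_by_activity`,
   `disease_genes` (with subtype expansion), `rank_targets_by_shared_drugs`.
6. **Graph mining** (`scb.graph_mining`) — project the RDF graph to a
   labeled entity network (interaction nodes contracted to edges), overlay
   precomputed structural-similarity pairs, and enumerate all bounded simple
   paths between two entities.
7. **Fixtures** (`scb.fixtures`) — a deterministic generator of synthetic
   source tables (PubChem-, DrugBank-, BindingDB-, CTD-, SIDER-like schemas)
   with a brute-forced ground-truth manifest, so the whole pipeline is
   testable offline.

The central property the toolkit maintains — and tests — is **integration
equivalence**: the ontology-level drug-target query returns exactly the
union of the per-source queries, for every drug, without naming any source.

## Worked example

The bundled worked example is a single compound–target association:
Troglitazone (PubChem CID 5591, ChEBI 9753) binding PPARG, tested in one
bioassay with a placeholder outcome and a publication reference.

```python
from scb.fixtures import worked_example
from scb.pipeline import annotate_directory
from scb import drug_targets, interaction_evidence

worked_example("example_src")           # writes TSVs + mapping.yaml
g = annotate_directory("example_src")   # annotate + materialize
print(f"{len(g)} triples ({len(g.inferred)} inferred)")
print(drug_targets(g, "Troglitazone"))
for row in interaction_evidence(g, "Troglitazone", "PPARG"):
    print(row)
```

prints

```
69 triples (17 inferred)
{'PPARG'}
{'description': 'Reporter-gene binding assay of Troglitazone vs PPARG',
 'measurement': 'EC50', 'relation': '=', 'value': 0.55, 'unit': 'um',
 'title': 'Synthetic placeholder reference'}
```

The 69 triples include the typed compound and protein nodes, the binding
interaction with two `has_participant` edges, the bioassay with its outcome
quadruple (EC50 = 0.55 um — a synthetic placeholder, not a measurement), the
publication xref, and the `UnificationXref` provenance nodes; the 17
inferred triples are the materialized broader types (a binding is a
chemical-protein interaction is an interaction), inverse `participates_in`
edges, and domain/range typings.  `drug_targets` asks only for a
chemical-protein interaction; it finds the leaf-typed binding because the
broader type was materialized.

The same flows are available from the shell:

```bash
scb build-ontology --format turtle -o schema.ttl
scb fixtures --seed 42 -o sources/
scb annotate --sources sources/ -o graph.ttl
scb query --template drug_targets_ontology --param label=Droxamib00 -i graph.ttl
scb paths --from compound44143441 --to proteinKCNH2_HUMAN --max-len 3 \
    -i fig6.ttl --similarity similarity.tsv --threshold 0.85
```

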