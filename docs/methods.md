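# Methods

## Data model

The schema is use-case driven rather than philosophically top-down: it holds
exactly the classes and properties the integrative queries need.
`SmallMolecule`, `Drug` and `Protein` sit under `PhysicalEntity`; `BioAssay`
and `Literature` under `Evidence`; `Disease`, `SideEffect` and `Pathway` are
atomic top-level classes (`Pathway` deliberately a black box — its instance
data is just a name).  Relations that carry context of their own
(experimental conditions, evidence, provenance) are reified as `Interaction`
subclasses — `DrugInducedSideEffect`, `DrugTreatment`, `DrugDrugInteraction`,
`ProteinProteinInteraction`, `ChemicalProteinInteraction` — linked to their
participants through the relation-ontology pair `has_participant` /
`participates_in`; context-free links stay plain object properties
(`has_go_annotation`, `has_associated_gene`, the transitive
`disease_subtype_of`).

Chemogenomic interactions are classified along two directions: how a
chemical acts on a protein (`ChemicalRegulatesProtein`: binding including
receptor agonist/antagonist activity, activity/expression/abundance/
stability regulation, covalent modification, folding, localization,
cleavage, splicing) and how a protein acts on a chemical
(`ProteinRegulatesChemical`: metabolism including oxidation/reduction/
hydrolysis/conjugation, transport, catalysis, abundance regulation,
binding).  The action vocabulary follows CTD-style interaction types.  The
full membership is a single versioned constant
(`ontology_schema.CHEMOGENOMIC_HIERARCHY`); a test audits that the count of
named classes strictly below `ChemicalProteinInteraction` is exactly 61.
External mappings (BioPAX, GO) are stored as annotations, not imports, so
building the schema never touches the network.

Utility classes are modeling artifacts, kept outside `PhysicalEntity`:
`ChemicalStructure` (format + representation; a molecule may carry several),
`PhysicalProperty` (e.g. molecular weight), `BioAssayOutcome` (measurement,
relation, value, unit — e.g. IC50 ≤ 10 um), `UnificationXref` (DB + ID +
comments: "this node equals that record over there") and `PublicationXref`
(the article that reported an assertion).

## Identifier unification

Primary identifier namespaces: PubChem CID for compounds, DrugBank ID for
drugs, UniProt entry name (matched case-insensitively, stored uppercase)
for proteins, UMLS for side effects, Disease Ontology ID for diseases,
plain names for pathways.  URIs are `base + kind-prefix + percent-encoded
id`, injective over (kind, id); the default base is
`http://chem2bio2rdf.org/chem2bio2owl#`.

Compound resolution order: explicit PubChem xref → InChI hit in an offline
lookup table (a pluggable stand-in for a live structure search) → surrogate
CID.  Surrogates are negative integers assigned in sorted key order
(InChI when present, else the source row key) across the whole ingest batch,
rendered `compoundF<n>`, so they are deterministic, order-independent and
can never collide with real CIDs.  Conflicting PubChem xrefs on one record
are an error, not a silent choice.

Free-text disease terms match in three passes: exact DOID; exact label or
synonym after lower-casing and punctuation stripping; token-set Jaccard
similarity with threshold 0.8 (chosen to accept word-order and inflection
noise like "Heart-Failure, Congestive" vs "congestive heart failure" while
rejecting single-shared-word coincidences), ties broken by lexicographically
smallest DOID.  An unmatched term is a logged skip, not an exception — one
dirty row should not abort a batch.

## Annotation

A mapping table declares, per source table, the record kind, the entity
kind and id column, the default interaction class, column→term assignments
and value maps for action-term columns.  Entity records become one typed
node each — exactly one asserted, most-specific `rdf:type`; broader types
appear only through reasoning, keeping the asserted/inferred split
auditable.  Interaction records become interaction nodes whose URI is
minted from (source, row id): the same participant pair asserted by two
sources — or twice by one — yields parallel interaction nodes on purpose,
because redundant database entries are corroborating evidence; entity
records resolving to one primary URI merge into one node with the union of
their xrefs.  Every interaction node carries a `UnificationXref` naming its
source table and row.

Outcome, xref, structure and property nodes are skolemized (SHA-1 of parent
URI + content) instead of blank, so re-annotating identical input is a
no-op and graphs diff cleanly.  Numeric fields that parse become
`xsd:decimal`; unparseable values are kept as plain-text literals — visible
to humans, invisible to numeric filters — rather than rejected.  Units are
stored verbatim with no nm↔um conversion; numeric comparisons are only
meaningful within one unit.

## Reasoning

The materializer is a closed, five-rule forward chainer run to least
fixpoint: subclass type propagation, subproperty propagation, inverse
completion, transitive closure, domain/range typing.  This RDFS-plus
profile covers every entailment the shipped queries rely on (leaf→branch
interaction typing, `participates_in` from `has_participant`, disease
subtype chains); there is no consistency checking, no property chains, no
cardinality reasoning.  Inferred triples carry a flag so exports can be
restricted to asserted facts (`--asserted-only`).  Soundness and
completeness are tested against an independent naive rule applier on random
instance graphs; monotonicity and idempotence are asserted directly.
Instances typed by classes the schema does not declare are warned about and
left un-propagated.

## Queries

`run_sparql` accepts the construct subset the shipped templates need —
basic graph patterns, FILTER, UNION, OPTIONAL, DISTINCT, GROUP BY/ORDER BY
and counting aggregates — and raises an explicit unsupported-feature error
for anything else (property paths, MINUS, SERVICE, named-graph blocks)
rather than risking silent mis-evaluation.

Evaluation installs a custom basic-graph-pattern evaluator: rdflib's
default statically sorts patterns by ground-term count, which disconnects
star-shaped queries and can build intermediate products with millions of
rows; ours orders patterns greedily so each one shares a variable with the
already-bound set, falling back to the most-ground pattern when starting a
new component.  Results are unchanged — only evaluation order differs — and
the per-source drug-target query drops from minutes to milliseconds on a
~12k-triple graph.

Operational choices: `ligands_by_activity` applies a *strict* weight
inequality (weight < cutoff excludes a compound at exactly the cutoff) and
reads SMILES only from structures tagged `openeye_can_smiles`;
`disease_genes` unions gene links over the materialized subtype closure
when expansion is on; `rank_targets_by_shared_drugs` links drugs to the
disease or any subtype via drug-induced-side-effect interactions, maps each
drug to its compound form through its PubChem unification xref, counts
distinct drugs per chemical-protein-interaction target, and sorts by
descending count with alphabetical label tie-break.

## Graph mining

The entity network keeps instance nodes only (molecules, drugs, proteins,
diseases, side effects, pathways, GO terms); interaction nodes are
contracted to edges labeled with their most specific asserted class
(multi-participant interactions become labeled cliques), annotation
properties keep their names as edge labels, and utility nodes are dropped.
Edges are undirected for mining — these are associations, not causal flows.
Structural-similarity pairs are input, not computed (fingerprinting is out
of scope); pairs at or above the threshold (default 0.85) overlay as
`similar_to` edges with the score retained.

`find_paths` enumerates all simple paths up to `max_len` edges (default 4:
the motifs of interest are length ≤ 3, and 4 gives headroom at tractable
cost), one result per distinct labeled path — parallel same-label edges from
redundant entries collapse, parallel different-label edges yield distinct
results — ordered by (length, node sequence, label sequence) and verified
against an exhaustive DFS oracle.

## Synthetic fixtures

The generator emulates the *shape* of public chemogenomics dumps, not their
content or scale: a CID-authoritative compound table with InChI/SMILES/
weight/ChEBI columns; two interaction sources with disjoint column
vocabularies, one CID-keyed with full assay outcomes (measurements drawn
from EC50/IC50/Ki/Kd, units um/nm, relations =/≤/≥), one InChI-keyed
expression/metabolism-style; drugs with PubChem xrefs; proteins with GO
annotations drawn from a small shared pool; a synonym-bearing disease tree;
drug–disease, drug–side-effect and disease–gene links; and similarity
pairs.  Default condition sizes (60 compounds, 12 drugs, 15 proteins, 120
interactions, 10 diseases, 15% surrogate fraction) keep every code path
exercised — all three compound-resolution branches, cross-source merging,
disease expansion, tie-breaks — at sub-second build times; the
integration-equivalence measurement uses a 200-compound, 300-interaction
variant.  Everything is byte-deterministic under a fixed seed.

`manifest.json` is ground truth recomputed from the emitted rows by brute
force (set unions, descendant DFS, bipartite counting, bounded path DFS
over canonical ids), independent of the RDF/SPARQL machinery it validates.

What passing on these fixtures does **not** show: behavior on real-scale
corpora (millions of triples), real chemistry (no structure normalization,
no tautomers, no real InChIs), real disease-vocabulary messiness beyond
case/punctuation/word-order noise, or schema drift in live sources.  Assay
outcome numbers — including the worked example's EC50 — are placeholders.

## Known limitations

- rdflib's in-memory store bounds practical graph size to a few hundred
  thousand triples; the design targets method correctness, not scale.
- The SPARQL subset excludes property paths; transitive queries rely on
  materialization instead.
- Disease matching is lexical; no embedding or trained similarity.
- Equivalent interaction entries across sources are never merged — by
  design — so evidence counting is per entry, not per distinct experiment.
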