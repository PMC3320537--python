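"""SPARQL execution and the case-study query patterns.

``run_sparql`` evaluates a query over the materialized graph through rdflib,
but first checks the parsed algebra against the supported construct subset
(basic graph patterns, FILTER, UNION, OPTIONAL, DISTINCT, GROUP BY and
ORDER BY, plus the aggregates needed for grouped counts).  Anything outside
that set — property paths, MINUS, SERVICE, named-graph blocks — raises
``UnsupportedFeatureError`` rather than silently mis-evaluating.

On top of it sit the integrative query patterns: drug → target search at the
ontology level or pinned to one source, interaction evidence with assay
outcomes and optional literature, agonist/antagonist ligand search with a
molecular-weight cut-off, disease → gene lookup with subtype expansion, and
ranking of targets by the number of disease-linked drugs they share.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from string import Template
from typing import Optional

from rdflib import Literal, URIRef
from rdflib.namespace import RDF, RDFS
from rdflib.plugins.sparql import prepareQuery
from rdflib.plugins.sparql.parserutils import CompValue
from rdflib.paths import Path

from .entity_resolution import mint_uri
from .errors import GraphLookupError, SchemaLookupError, UnsupportedFeatureError
from .namespaces import RO, core
from .ontology_schema import OntologySchema, descendants
from .semgraph import SemanticGraph

__all__ = [
    "QueryTemplate",
    "RankedTarget",
    "TEMPLATES",
    "run_sparql",
    "drug_targets",
    "drug_targets_by_source",
    "interaction_evidence",
    "ligands_by_activity",
    "disease_genes",
    "rank_targets_by_shared_drugs",
]

# Algebra node names rdflib produces for the supported construct set.
_ALLOWED = {
    "SelectQuery", "Project", "Distinct", "Reduced", "Slice",
    "BGP", "Filter", "Union", "Join", "LeftJoin", "ToMultiSet",
    "OrderBy", "OrderCondition", "Group", "AggregateJoin", "Extend",
    "Aggregate_Count", "Aggregate_Sample", "values", "Values", "ToList",
    "TrueFilter", "vars",
}


def _check_algebra(node) -> None:
    if isinstance(node, CompValue):
        name = node.name
        if name not in _ALLOWED and not name.startswith(
            ("Builtin_", "RelationalExpression", "ConditionalAndExpression",
             "ConditionalOrExpression", "UnaryNot", "MultiplicativeExpression",
             "AdditiveExpression", "Function", "UnaryMinus", "UnaryPlus")
        ):
            raise UnsupportedFeatureError(f"SPARQL construct {name!r} is not supported")
        for v in node.values():
            _check_algebra(v)
    elif isinstance(node, Path):
        raise UnsupportedFeatureError("property paths are not supported")
    elif isinstance(node, (list, tuple, set)):
        for v in node:
            _check_algebra(v)


def _connected_bgp_eval(ctx, part):
    """Join-order-aware BGP evaluation, registered as a custom evaluator.

    rdflib's default BGP evaluation statically sorts triple patterns by the
    number of ground terms, which tears star-shaped queries apart and can
    build cross products with millions of intermediate rows.  This evaluator
    orders patterns greedily instead: always pick a pattern that shares a
    variable with what is already bound (falling back to the most-ground
    pattern when starting a new component), so each join step stays
    selective.  Results are identical — only the evaluation order changes.
    """
    from rdflib.plugins.sparql.evaluate import evalBGP
    from rdflib.term import BNode, Variable

    if part.name != "BGP":
        raise NotImplementedError

    remaining = list(part.triples)
    bound = set()
    for t in remaining:
        for n in t:
            if isinstance(n, (Variable, BNode)) and ctx[n] is not None:
                bound.add(n)
    ordered = []
    while remaining:
        def key(t):
            tvars = {n for n in t if isinstance(n, (Variable, BNode))}
            unbound = len(tvars - bound)
            connected = unbound == 0 or bool(tvars & bound) or not ordered
            return (not connected, unbound)
        best = min(remaining, key=key)
        remaining.remove(best)
        ordered.append(best)
        bound |= {n for n in best if isinstance(n, (Variable, BNode))}
    return evalBGP(ctx, ordered)


def _install_bgp_evaluator() -> None:
    from rdflib.plugins.sparql import CUSTOM_EVALS

    CUSTOM_EVALS.setdefault("scb_connected_bgp", _connected_bgp_eval)


_install_bgp_evaluator()


def run_sparql(graph: SemanticGraph, query: str, bindings: Optional[dict] = None):
    """Evaluate ``query`` over the graph; returns an rdflib Result.

    Raises a parse error (with position) on bad syntax and
    ``UnsupportedFeatureError`` on constructs outside the supported subset.
    """
    prepared = prepareQuery(query)
    _check_algebra(prepared.algebra)
    return graph.graph.query(prepared, initBindings=bindings or {})


@dataclass(frozen=True)
class QueryTemplate:
    """A named, parameterized SPARQL query; ``$name`` placeholders."""

    name: str
    sparql_text: str
    params: tuple[tuple[str, str], ...] = ()

    def render(self, **values: str) -> str:
        missing = [p for p, _ in self.params if p not in values]
        if missing:
            raise KeyError(f"template {self.name}: missing params {missing}")
        return Template(self.sparql_text).substitute(**values)


def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace('"', '\\"')


_PREFIXES = """\
PREFIX c2b2r: <$base>
PREFIX ro: <http://www.obofoundry.org/ro/ro.owl#>
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>
"""

#: The shipped template set; the two drug-target patterns mirror the
#: source-union and ontology-level formulations whose equivalence is the
#: integration claim this package tests.
TEMPLATES: dict[str, QueryTemplate] = {}


def _template(name, body, params):
    TEMPLATES[name] = QueryTemplate(name, _PREFIXES + body, tuple(params))


_template(
    "drug_targets_ontology",
    """\
SELECT DISTINCT ?target ?target_name
WHERE {
  ?chemical rdfs:label "$label" ;
            ro:participates_in ?interaction .
  ?interaction rdf:type c2b2r:ChemicalProteinInteraction ;
               ro:has_participant ?target .
  ?target rdf:type c2b2r:Protein ;
          rdfs:label ?target_name .
}
""",
    [("base", "uri"), ("label", "string")],
)

_template(
    "drug_targets_by_source",
    """\
SELECT DISTINCT ?target ?target_name
WHERE {
  ?chemical rdfs:label "$label" ;
            ro:participates_in ?interaction .
  ?interaction rdf:type c2b2r:ChemicalProteinInteraction ;
               ro:has_participant ?target ;
               c2b2r:xref ?src .
  ?src c2b2r:DB "$source" .
  ?target rdf:type c2b2r:Protein ;
          rdfs:label ?target_name .
}
""",
    [("base", "uri"), ("label", "string"), ("source", "string")],
)

_template(
    "drug_targets_union_of_sources",
    """\
SELECT DISTINCT ?target ?target_name
WHERE {
  {
    ?chemical rdfs:label "$label" ; ro:participates_in ?interaction .
    ?interaction rdf:type c2b2r:ChemicalProteinInteraction ;
                 ro:has_participant ?target ; c2b2r:xref ?src .
    ?src c2b2r:DB "$source_a" .
    ?target rdf:type c2b2r:Protein ; rdfs:label ?target_name .
  }
  UNION
  {
    ?chemical rdfs:label "$label" ; ro:participates_in ?interaction .
    ?interaction rdf:type c2b2r:ChemicalProteinInteraction ;
                 ro:has_participant ?target ; c2b2r:xref ?src .
    ?src c2b2r:DB "$source_b" .
    ?target rdf:type c2b2r:Protein ; rdfs:label ?target_name .
  }
}
""",
    [("base", "uri"), ("label", "string"), ("source_a", "string"), ("source_b", "string")],
)

_template(
    "interaction_evidence",
    """\
SELECT ?description ?measurement ?relation ?value ?unit ?title
WHERE {
  ?chemical rdfs:label "$chemical" ;
            ro:participates_in ?interaction .
  ?interaction rdf:type c2b2r:ChemicalProteinInteraction ;
               ro:has_participant ?target ;
               c2b2r:evidence ?bioAssay .
  ?target rdfs:label "$protein" .
  ?bioAssay rdf:type c2b2r:BioAssay .
  OPTIONAL { ?bioAssay c2b2r:description ?description }
  OPTIONAL {
    ?bioAssay c2b2r:hasOutcome ?outcome .
    ?outcome c2b2r:measurement ?measurement ;
             c2b2r:relation ?relation ;
             c2b2r:value ?value ;
             c2b2r:unit ?unit .
  }
  OPTIONAL { ?bioAssay c2b2r:xref ?pub . ?pub c2b2r:title ?title }
}
ORDER BY ?description ?measurement
""",
    [("base", "uri"), ("chemical", "string"), ("protein", "string")],
)

_template(
    "ligands_by_activity",
    """\
SELECT DISTINCT ?chemical ?structureData
WHERE {
  ?interaction rdf:type c2b2r:$activity_class ;
               ro:has_participant ?chemical ;
               ro:has_participant ?target .
  ?target rdfs:label "$protein" .
  ?chemical rdf:type c2b2r:SmallMolecule ;
            c2b2r:hasPhysicalProperty ?prop .
  ?prop c2b2r:molecularWeight ?weight .
  OPTIONAL {
    ?chemical c2b2r:structure ?st .
    ?st c2b2r:structureFormat "openeye_can_smiles"^^xsd:string ;
        c2b2r:structureData ?structureData .
  }
  FILTER(?weight < $max_weight)
}
""",
    [("base", "uri"), ("activity_class", "term"), ("protein", "string"),
     ("max_weight", "decimal")],
)


# ---------------------------------------------------------------------------
# Convenience operations over the templates
# ---------------------------------------------------------------------------

def _base(graph: SemanticGraph) -> str:
    return graph.schema.base if graph.schema else \
        "http://chem2bio2rdf.org/chem2bio2owl#"


def drug_targets(graph: SemanticGraph, drug_label: str) -> set[str]:
    """Protein labels participating in any chemical-protein interaction
    (any subclass, via materialized typing) with the labeled chemical."""
    q = TEMPLATES["drug_targets_ontology"].render(
        base=_base(graph), label=_escape(drug_label))
    return {str(row.target_name) for row in run_sparql(graph, q)}


def drug_targets_by_source(graph: SemanticGraph, drug_label: str, source: str) -> set[str]:
    """Same search restricted to interactions asserted by one source."""
    q = TEMPLATES["drug_targets_by_source"].render(
        base=_base(graph), label=_escape(drug_label), source=_escape(source))
    return {str(row.target_name) for row in run_sparql(graph, q)}


def interaction_evidence(
    graph: SemanticGraph, chemical_label: str, protein_label: str
) -> list[dict]:
    """One row per evidence assay for the pair, with the outcome quadruple
    and the article title when a publication xref exists."""
    q = TEMPLATES["interaction_evidence"].render(
        base=_base(graph), chemical=_escape(chemical_label),
        protein=_escape(protein_label))
    rows = []
    for row in run_sparql(graph, q):
        rows.append({
            "description": str(row.description) if row.description is not None else None,
            "measurement": str(row.measurement) if row.measurement is not None else None,
            "relation": str(row.relation) if row.relation is not None else None,
            "value": row.value.toPython() if row.value is not None else None,
            "unit": str(row.unit) if row.unit is not None else None,
            "title": str(row.title) if row.title is not None else None,
        })
    return rows


_TERM_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def ligands_by_activity(
    graph: SemanticGraph,
    protein_label: str,
    activity_class: str,
    max_weight: float,
) -> set[tuple[str, Optional[str]]]:
    """Compounds showing ``activity_class`` against the protein, restricted
    to molecular weight strictly below ``max_weight``; returns (compound URI,
    canonical SMILES or None)."""
    schema = graph.schema
    if schema is None or not _TERM_RE.match(activity_class) or \
            activity_class not in schema.classes:
        raise SchemaLookupError(activity_class)
    if activity_class != "ChemicalProteinInteraction" and \
            activity_class not in descendants(schema, "ChemicalProteinInteraction"):
        raise SchemaLookupError(
            f"{activity_class} is not a chemical-protein interaction class")
    q = TEMPLATES["ligands_by_activity"].render(
        base=_base(graph), activity_class=activity_class,
        protein=_escape(protein_label), max_weight=repr(float(max_weight)))
    out = set()
    for row in run_sparql(graph, q):
        smiles = str(row.structureData) if row.structureData is not None else None
        out.add((str(row.chemical), smiles))
    return out


# ---------------------------------------------------------------------------
# Disease-centric operations (python over triples; the disease tree is
# materialized via the transitive subtype property)
# ---------------------------------------------------------------------------

def _disease_uri(graph: SemanticGraph, term: str) -> URIRef:
    base = _base(graph)
    c2 = core(base)
    if term.upper().startswith("DOID"):
        uri = URIRef(mint_uri("disease", term, base))
        if graph.has_node(uri):
            return uri
    for s in graph.graph.subjects(RDFS.label, Literal(term)):
        if (s, RDF.type, c2["Disease"]) in graph.graph:
            return s
    raise GraphLookupError(f"disease term {term!r} not in graph")


def _disease_descendants(graph: SemanticGraph, uri: URIRef) -> set[URIRef]:
    c2 = core(_base(graph))
    return set(graph.graph.subjects(c2["disease_subtype_of"], uri))


def disease_genes(graph: SemanticGraph, disease_term: str, expand: bool = True) -> set[str]:
    """URIs of genes/proteins associated with a disease; with ``expand`` the
    association is unioned over all subtype diseases (materialized closure)."""
    c2 = core(_base(graph))
    root = _disease_uri(graph, disease_term)
    diseases = {root} | (_disease_descendants(graph, root) if expand else set())
    genes: set[str] = set()
    for d in diseases:
        for g in graph.graph.objects(d, c2["has_associated_gene"]):
            genes.add(str(g))
    return genes


@dataclass(frozen=True)
class RankedTarget:
    """A protein ranked by how many disease-linked drugs hit it."""

    target: str
    label: str
    shared_drug_count: int


def rank_targets_by_shared_drugs(
    graph: SemanticGraph, disease_term: str
) -> list[RankedTarget]:
    """Rank targets of disease-linked drugs by shared-drug count.

    Drugs are linked to the disease (or any subtype) through drug-induced
    side-effect interactions; each drug maps to its compound form through
    its PubChem unification xref, targets come from chemical-protein
    interactions, and targets are sorted by descending distinct-drug count
    with alphabetical label tie-break.
    """
    base = _base(graph)
    c2 = core(base)
    schema = graph.schema
    root = _disease_uri(graph, disease_term)
    diseases = {root} | _disease_descendants(graph, root)

    dise_cls = schema.class_uri("DrugInducedSideEffect") if schema else c2["DrugInducedSideEffect"]
    drug_cls = schema.class_uri("Drug") if schema else c2["Drug"]
    cpi_cls = (schema.class_uri("ChemicalProteinInteraction") if schema
               else c2["ChemicalProteinInteraction"])
    prot_cls = schema.class_uri("Protein") if schema else c2["Protein"]

    drugs: set[URIRef] = set()
    for i in graph.graph.subjects(RDF.type, dise_cls):
        parts = set(graph.graph.objects(i, RO["has_participant"]))
        if parts & diseases:
            drugs |= {p for p in parts if (p, RDF.type, drug_cls) in graph.graph}

    # Drug → chemical forms: the drug node itself plus any compound node it
    # unifies with through a PubChem xref.
    chem_forms: dict[URIRef, set[URIRef]] = {}
    for d in drugs:
        forms = {d}
        for x in graph.graph.objects(d, c2["xref"]):
            db = graph.graph.value(x, c2["DB"])
            cid = graph.graph.value(x, c2["ID"])
            if db is not None and str(db).lower() == "pubchem" and cid is not None:
                forms.add(URIRef(mint_uri("compound", str(cid), base)))
        chem_forms[d] = forms

    target_drugs: dict[URIRef, set[URIRef]] = {}
    for d, forms in chem_forms.items():
        for form in forms:
            for i in graph.graph.subjects(RO["has_participant"], form):
                if (i, RDF.type, cpi_cls) not in graph.graph:
                    continue
                for t in graph.graph.objects(i, RO["has_participant"]):
                    if t != form and (t, RDF.type, prot_cls) in graph.graph:
                        target_drugs.setdefault(t, set()).add(d)

    ranked = []
    for t, ds in target_drugs.items():
        label = graph.graph.value(t, RDFS.label)
        ranked.append(RankedTarget(str(t), str(label) if label else str(t), len(ds)))
    ranked.sort(key=lambda r: (-r.shared_drug_count, r.label))
    return ranked
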