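"""Ontology population: turn mapped source records into RDF instances.

Each entity record becomes one typed instance (one asserted, most-specific
``rdf:type``) carrying labels, data properties, chemical-structure and
physical-property utility nodes and UnificationXref provenance.  Each
interaction record becomes a first-class interaction node with
``has_participant`` edges to resolved participants, optional BioAssay
evidence with an outcome quadruple (measurement, relation, value, unit) and
PublicationXref references, plus a UnificationXref naming the source table
and row it came from.  Interaction nodes from distinct (source, record)
pairs are deliberately kept as parallel nodes even when their participants
coincide — redundant database entries are evidence, not noise — whereas
entity records that resolve to one primary URI merge into a single node.

Utility nodes (xrefs, outcomes, structures) use skolem URIs hashed from the
parent URI plus content, so re-annotating identical input is a no-op and
graphs diff cleanly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from rdflib import Literal, URIRef
from rdflib.namespace import RDF, RDFS, XSD

from .entity_resolution import (
    CompoundResolver,
    DiseaseTermTable,
    ResolvedEntity,
    XRef,
    mint_uri,
    resolve_disease,
    resolve_simple,
)
from .errors import ConfigurationError, GraphLookupError
from .namespaces import DEFAULT_BASE, RO, core
from .ontology_schema import OntologySchema
from .semgraph import SemanticGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SourceRecord",
    "SourceMapping",
    "MappingTable",
    "ResolutionContext",
    "annotate",
    "attach_provenance",
    "deduplicate",
]

#: Mapping targets understood by the annotator beyond bare schema terms.
#: ``xref:<DB>`` is also accepted for unification cross-references.
RESERVED_TERMS = {
    "label",              # rdfs:label
    "interaction_type",   # column holds a source action term; value-mapped to a class
    "inchi",              # compound InChI: used for resolution + ChemicalStructure
    "smiles",             # ChemicalStructure with format "openeye_can_smiles"
    "pubmed_id",          # PublicationXref ID
    "go_terms",           # pipe-separated GO annotations on a protein
    "disease_parent",     # parent DOID → disease_subtype_of link
    "disease_gene",       # entry name of a gene associated with a disease
    "synonyms",           # retained as comments only
    "ignore",
}

_ENTITY_CLASS = {
    "compound": "SmallMolecule",
    "drug": "Drug",
    "protein": "Protein",
    "disease": "Disease",
    "side_effect": "SideEffect",
    "pathway": "Pathway",
    "literature": "Literature",
}

_PARTICIPANT_CLASSES = {"SmallMolecule", "Drug", "Protein", "Disease", "SideEffect", "Pathway"}


@dataclass(frozen=True)
class SourceRecord:
    """One row of a source dump, keyed by (source, record_id)."""

    source: str
    record_id: str
    record_kind: str  # "entity" | "interaction"
    fields: Mapping[str, str] = field(default_factory=dict)


@dataclass
class SourceMapping:
    """Column → ontology-term mapping for one source table."""

    record_kind: str
    entity_kind: Optional[str] = None          # for entity sources
    id_column: Optional[str] = None
    interaction_class: Optional[str] = None    # default class when no type column
    columns: dict[str, str] = field(default_factory=dict)
    value_maps: dict[str, dict[str, str]] = field(default_factory=dict)


@dataclass
class MappingTable:
    """All source mappings for an ingest batch; validated against the schema."""

    sources: dict[str, SourceMapping] = field(default_factory=dict)

    @property
    def entries(self) -> dict[tuple[str, str], str]:
        return {(s, col): term
                for s, m in self.sources.items() for col, term in m.columns.items()}

    def validate(self, schema: OntologySchema) -> None:
        for (source, col), term in self.entries.items():
            if term in RESERVED_TERMS or term.startswith("xref:"):
                continue
            if term not in schema.classes and term not in schema.properties:
                raise ConfigurationError(
                    f"mapping {source}.{col} → {term!r}: term not in schema"
                )
        for source, m in self.sources.items():
            for col, vmap in m.value_maps.items():
                for value, cls in vmap.items():
                    if cls not in schema.classes:
                        raise ConfigurationError(
                            f"value map {source}.{col}: {value!r} → {cls!r} not in schema"
                        )
            if m.interaction_class and m.interaction_class not in schema.classes:
                raise ConfigurationError(
                    f"source {source}: interaction_class {m.interaction_class!r} not in schema"
                )

    @classmethod
    def from_dict(cls, data: Mapping) -> "MappingTable":
        table = cls()
        for name, spec in data.get("sources", {}).items():
            table.sources[name] = SourceMapping(
                record_kind=spec["record_kind"],
                entity_kind=spec.get("entity_kind"),
                id_column=spec.get("id_column"),
                interaction_class=spec.get("interaction_class"),
                columns=dict(spec.get("columns", {})),
                value_maps={c: dict(v) for c, v in spec.get("value_maps", {}).items()},
            )
        return table


@dataclass
class ResolutionContext:
    """Shared resolvers handed to :func:`annotate`."""

    compounds: CompoundResolver = field(default_factory=CompoundResolver)
    do_terms: DiseaseTermTable = field(default_factory=DiseaseTermTable)
    disease_threshold: float = 0.8
    base: str = DEFAULT_BASE


def _skolem(prefix: str, *parts: str, base: str = DEFAULT_BASE) -> URIRef:
    digest = hashlib.sha1("\x00".join(parts).encode()).hexdigest()[:16]
    return URIRef(f"{base}{prefix}{digest}")


def _decimal_or_text(raw: str) -> Literal:
    """Numbers become xsd:decimal; unparseable values stay plain text so
    numeric FILTERs skip them instead of mis-comparing."""
    try:
        return Literal(float(raw), datatype=XSD.decimal)
    except (TypeError, ValueError):
        return Literal(raw)


# ---------------------------------------------------------------------------
# annotate
# ---------------------------------------------------------------------------

def annotate(
    records: Sequence[SourceRecord],
    mapping: MappingTable,
    schema: OntologySchema,
    resolvers: Optional[ResolutionContext] = None,
) -> SemanticGraph:
    """Populate a :class:`SemanticGraph` from mapped source records.

    Deterministic for fixed input: surrogate CIDs are pre-assigned over the
    whole batch in sorted-key order before any record is written.  Records
    whose participants cannot be resolved are skipped with a logged reason;
    columns with no mapping entry are logged and ignored.
    """
    ctx = resolvers or ResolutionContext()
    mapping.validate(schema)
    c2 = core(ctx.base)

    # Pre-pass: register every compound key so surrogate numbering does not
    # depend on record order.
    keys = []
    for rec in records:
        m = mapping.sources.get(rec.source)
        if m is None:
            continue
        for col, raw in rec.fields.items():
            raw = (raw or "").strip()
            if m.columns.get(col) != "inchi" or not raw:
                continue
            if raw in ctx.compounds.lookup.inchi_to_cid:
                continue
            has_cid = any(
                (rec.fields.get(c) or "").strip()
                for c, t in m.columns.items() if t == "SmallMolecule"
            ) or bool((rec.fields.get(m.id_column or "") or "").strip()
                      if m.entity_kind == "compound" else False)
            if not has_cid:
                keys.append(raw)
    ctx.compounds.assign_surrogates(keys)

    sg = SemanticGraph(schema=schema)
    for rec in records:
        m = mapping.sources.get(rec.source)
        if m is None:
            logger.warning("source %r has no mapping; record %s skipped",
                           rec.source, rec.record_id)
            continue
        unmapped = set(rec.fields) - set(m.columns) - {m.id_column}
        for col in sorted(unmapped):
            logger.info("unmapped column %s.%s skipped", rec.source, col)
        if m.record_kind == "entity":
            _annotate_entity(sg, rec, m, schema, ctx, c2)
        else:
            _annotate_interaction(sg, rec, m, schema, ctx, c2)
    return sg


def _resolve_entity_record(rec, m, ctx) -> Optional[ResolvedEntity]:
    kind = m.entity_kind
    pid = rec.fields.get(m.id_column or "", "").strip()
    extra_xrefs = [
        XRef(term[5:], rec.fields[col].strip())
        for col, term in sorted(m.columns.items())
        if term.startswith("xref:") and rec.fields.get(col, "").strip()
    ]
    if kind == "compound":
        inchi = next((rec.fields.get(c, "").strip() or None
                      for c, t in m.columns.items() if t == "inchi"), None)
        xrefs = ([XRef("PubChem", pid)] if pid else []) + extra_xrefs
        if not xrefs and inchi is None:
            logger.warning("compound record %s/%s has no identifier; skipped",
                           rec.source, rec.record_id)
            return None
        return ctx.compounds.resolve(xrefs=xrefs, inchi=inchi,
                                     source_key=f"{rec.source}:{rec.record_id}")
    if kind == "disease" and not pid.upper().startswith("DOID"):
        ent = resolve_disease(pid, ctx.do_terms, ctx.disease_threshold, ctx.base)
        if ent is not None:
            ent.xrefs.extend(extra_xrefs)
        return ent
    if not pid:
        logger.warning("record %s/%s lacks id column; skipped", rec.source, rec.record_id)
        return None
    xrefs = [XRef(rec.source, pid)] + extra_xrefs
    return resolve_simple(kind, pid, ctx.base, xrefs=xrefs)


def _annotate_entity(sg, rec, m, schema, ctx, c2) -> None:
    ent = _resolve_entity_record(rec, m, ctx)
    if ent is None:
        return
    uri = URIRef(ent.uri)
    sg.add((uri, RDF.type, schema.class_uri(_ENTITY_CLASS[ent.kind])))
    if ent.kind == "compound":
        sg.add((uri, c2["CID"], Literal(int(ent.primary_id), datatype=XSD.integer)))
    _apply_columns(sg, uri, rec, m, schema, ctx, c2)
    attach_provenance(sg, uri, ent.xrefs, kind="unification", base=ctx.base)


def _apply_columns(sg, uri, rec, m, schema, ctx, c2) -> None:
    for col in sorted(m.columns):
        term = m.columns[col]
        raw = rec.fields.get(col, "").strip()
        if not raw or term in ("ignore", "interaction_type") or term.startswith("xref:"):
            continue
        if term == "label":
            sg.add((uri, RDFS.label, Literal(raw)))
        elif term == "synonyms":
            for syn in raw.split("|"):
                if syn:
                    sg.add((uri, c2["comments"], Literal(f"synonym: {syn}")))
        elif term == "inchi":
            _structure_node(sg, uri, "standard_inchi", raw, ctx.base, c2, schema)
        elif term == "smiles":
            _structure_node(sg, uri, "openeye_can_smiles", raw, ctx.base, c2, schema)
        elif term == "molecularWeight":
            prop = _skolem("physprop", str(uri), raw, base=ctx.base)
            sg.add((prop, RDF.type, schema.class_uri("PhysicalProperty")))
            sg.add((prop, c2["molecularWeight"], _decimal_or_text(raw)))
            sg.add((uri, c2["hasPhysicalProperty"], prop))
        elif term == "go_terms":
            for go in sorted(t for t in raw.split("|") if t):
                go_uri = URIRef(mint_uri("go_term", go.replace(":", "_"), ctx.base))
                sg.add((go_uri, RDF.type, schema.class_uri("GeneOntologyTerm")))
                sg.add((go_uri, RDFS.label, Literal(go)))
                sg.add((uri, c2["has_go_annotation"], go_uri))
        elif term == "disease_parent":
            parent = URIRef(mint_uri("disease", raw, ctx.base))
            sg.add((uri, c2["disease_subtype_of"], parent))
        elif term == "disease_gene":
            gene = resolve_simple("protein", raw, ctx.base)
            sg.add((uri, c2["has_associated_gene"], URIRef(gene.uri)))
        elif term in schema.properties:
            kind = schema.properties[term].kind
            if kind == "data-property":
                rng = schema.properties[term].range
                lit = _decimal_or_text(raw) if rng in ("decimal", "integer") else Literal(raw)
                sg.add((uri, schema.property_uri(term), lit))
            else:
                logger.info("object-property column %s.%s ignored on entity", rec.source, col)
        elif term in schema.classes:
            pass  # participant columns are handled by the interaction path
        else:  # pragma: no cover - mapping.validate rules this out
            logger.warning("unhandled mapping target %r", term)


def _structure_node(sg, parent, fmt, data, base, c2, schema) -> None:
    node = _skolem("structure", str(parent), fmt, data, base=base)
    sg.add((node, RDF.type, schema.class_uri("ChemicalStructure")))
    sg.add((node, c2["structureFormat"], Literal(fmt, datatype=XSD.string)))
    sg.add((node, c2["structureData"], Literal(data)))
    sg.add((parent, c2["structure"], node))


def _annotate_interaction(sg, rec, m, schema, ctx, c2) -> None:
    # Resolve participants first; an unresolvable participant skips the record.
    participants: list[tuple[str, ResolvedEntity]] = []
    for col in sorted(m.columns):
        term = m.columns[col]
        raw = rec.fields.get(col, "").strip()
        if term not in _PARTICIPANT_CLASSES:
            continue
        if not raw:
            logger.warning("interaction %s/%s: empty participant column %s; skipped",
                           rec.source, rec.record_id, col)
            return
        if term == "SmallMolecule":
            ent = ctx.compounds.resolve(xrefs=[XRef("PubChem", raw)])
        elif term == "Drug":
            ent = resolve_simple("drug", raw, ctx.base)
        elif term == "Protein":
            ent = resolve_simple("protein", raw, ctx.base)
        elif term == "Disease":
            ent = (resolve_simple("disease", raw, ctx.base)
                   if raw.upper().startswith("DOID")
                   else resolve_disease(raw, ctx.do_terms, ctx.disease_threshold, ctx.base))
            if ent is None:
                logger.warning("interaction %s/%s: disease %r unresolved; skipped",
                               rec.source, rec.record_id, raw)
                return
        elif term == "SideEffect":
            ent = resolve_simple("side_effect", raw, ctx.base)
        else:
            ent = resolve_simple("pathway", raw, ctx.base)
        participants.append((term, ent))

    # InChI-keyed compound reference (sources without a CID column).
    if not any(t == "SmallMolecule" for t, _ in participants):
        for col in sorted(m.columns):
            if m.columns[col] == "inchi":
                raw = rec.fields.get(col, "").strip()
                if raw:
                    participants.append(("SmallMolecule", ctx.compounds.resolve(inchi=raw)))
    if not participants:
        logger.warning("interaction %s/%s has no participants; skipped",
                       rec.source, rec.record_id)
        return

    # Interaction class: value-mapped action term, else the source default.
    icls = m.interaction_class or "Interaction"
    for col, term in m.columns.items():
        if term == "interaction_type":
            raw = rec.fields.get(col, "").strip()
            vmap = m.value_maps.get(col, {})
            if raw in vmap:
                icls = vmap[raw]
            elif raw:
                logger.info("unmapped action term %r; using %s", raw, icls)

    iuri = URIRef(mint_uri("interaction", f"{rec.source}_{rec.record_id}", ctx.base))
    sg.add((iuri, RDF.type, schema.class_uri(icls)))
    for _, ent in participants:
        puri = URIRef(ent.uri)
        sg.add((iuri, RO["has_participant"], puri))
        if not sg.asserted_types(puri):
            sg.add((puri, RDF.type, schema.class_uri(_ENTITY_CLASS[ent.kind])))

    # Evidence: a BioAssay node when any assay/outcome column is populated.
    f = {m.columns.get(c): rec.fields.get(c, "").strip() for c in m.columns}
    assay_fields = {k: v for k, v in f.items()
                    if k in ("description", "measurement", "relation", "value", "unit") and v}
    if assay_fields:
        assay = _skolem("bioassay", str(iuri), base=ctx.base)
        sg.add((assay, RDF.type, schema.class_uri("BioAssay")))
        sg.add((iuri, c2["evidence"], assay))
        if "description" in assay_fields:
            sg.add((assay, c2["description"], Literal(assay_fields["description"])))
        outcome_fields = {k: v for k, v in assay_fields.items() if k != "description"}
        if outcome_fields:
            outcome = _skolem("outcome", str(assay),
                              *sorted(f"{k}={v}" for k, v in outcome_fields.items()),
                              base=ctx.base)
            sg.add((outcome, RDF.type, schema.class_uri("BioAssayOutcome")))
            sg.add((assay, c2["hasOutcome"], outcome))
            for k, v in outcome_fields.items():
                lit = _decimal_or_text(v) if k == "value" else Literal(v)
                sg.add((outcome, c2[k], lit))
        pub_anchor = assay
    else:
        pub_anchor = iuri

    pmid = f.get("pubmed_id", "")
    if pmid:
        x = XRef("PubMed", pmid, comments=f.get("title") or None)
        attach_provenance(sg, pub_anchor, [x], kind="publication", base=ctx.base)

    # Source provenance: every interaction names the table row it came from.
    src_xref = XRef(rec.source, rec.record_id)
    attach_provenance(sg, iuri, [src_xref], kind="unification", base=ctx.base)
    sg.provenance.setdefault(str(iuri), []).append(src_xref)


# ---------------------------------------------------------------------------
# provenance + deduplication
# ---------------------------------------------------------------------------

def attach_provenance(
    graph: SemanticGraph,
    entity_uri,
    xrefs: Sequence[XRef],
    kind: str = "unification",
    base: str = DEFAULT_BASE,
) -> SemanticGraph:
    """Attach UnificationXref / PublicationXref nodes to an entity.

    One node per distinct (DB, ID); duplicates collapse by construction
    because the node URI is a hash of parent + content.  An empty xref list
    leaves the graph unchanged; an unknown entity raises GraphLookupError.
    """
    if not xrefs:
        return graph
    uri = URIRef(entity_uri)
    if not graph.has_node(uri):
        raise GraphLookupError(str(entity_uri))
    schema = graph.schema
    c2 = core(base)
    cls = "UnificationXref" if kind == "unification" else "PublicationXref"
    prefix = "unifxref" if kind == "unification" else "pubxref"
    cls_uri = schema.class_uri(cls) if schema else c2[cls]
    seen = set()
    for x in xrefs:
        if (x.DB, x.ID) in seen:
            continue
        seen.add((x.DB, x.ID))
        node = _skolem(prefix, str(uri), x.DB, x.ID, base=base)
        graph.add((node, RDF.type, cls_uri))
        graph.add((node, c2["DB"], Literal(x.DB)))
        graph.add((node, c2["ID"], Literal(x.ID)))
        if x.comments:
            if kind == "publication":
                graph.add((node, c2["title"], Literal(x.comments)))
            else:
                graph.add((node, c2["comments"], Literal(x.comments)))
        graph.add((uri, c2["xref"], node))
    return graph


def deduplicate(graph: SemanticGraph) -> SemanticGraph:
    """Collapse redundant assertions; idempotent.

    RDF set semantics already merge identical triples and same-URI entities
    (entity URIs are minted from primary IDs, so cross-source duplicates of
    one compound land on one node with the union of xrefs).  Interaction
    nodes are keyed by (source, record), so parallel database entries for
    the same participant pair are preserved as distinct nodes.  This pass
    therefore only normalizes the provenance map.
    """
    for uri, xs in graph.provenance.items():
        unique, seen = [], set()
        for x in xs:
            if (x.DB, x.ID) not in seen:
                seen.add((x.DB, x.ID))
                unique.append(x)
        graph.provenance[uri] = unique
    return graph
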