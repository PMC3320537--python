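"""Ontology population: instances, evidence, provenance, deduplication."""

import hashlib

import pytest
from rdflib import Literal, URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import RDF, RDFS, XSD

from scb.annotation import (
    MappingTable,
    ResolutionContext,
    SourceMapping,
    SourceRecord,
    annotate,
    attach_provenance,
    deduplicate,
)
from scb.entity_resolution import XRef
from scb.errors import GraphLookupError
from scb.namespaces import DEFAULT_BASE, RO, core

C2 = core(DEFAULT_BASE)


def compound_mapping():
    return MappingTable(sources={
        "src": SourceMapping(
            record_kind="entity", entity_kind="compound", id_column="cid",
            columns={"label": "label"}),
    })


class TestWorkedExampleGraph:
    """The Troglitazone/PPARG binding record and its ontological footprint."""

    def test_one_binding_interaction_two_participants(self, worked_graph, schema):
        binding = schema.class_uri("ChemicalBindsProtein")
        nodes = list(worked_graph.graph.subjects(RDF.type, binding))
        assert len(nodes) == 1
        parts = set(worked_graph.graph.objects(nodes[0], RO["has_participant"]))
        assert parts == {URIRef(DEFAULT_BASE + "compound5591"),
                         URIRef(DEFAULT_BASE + "proteinPPARG_HUMAN")}

    def test_evidence_chain_assay_outcome(self, worked_graph, schema):
        binding = schema.class_uri("ChemicalBindsProtein")
        (inode,) = worked_graph.graph.subjects(RDF.type, binding)
        assays = list(worked_graph.graph.objects(inode, C2["evidence"]))
        assert len(assays) == 1
        (outcome,) = worked_graph.graph.objects(assays[0], C2["hasOutcome"])
        assert str(worked_graph.graph.value(outcome, C2["measurement"])) == "EC50"
        assert str(worked_graph.graph.value(outcome, C2["relation"])) == "="
        assert worked_graph.graph.value(outcome, C2["value"]).toPython() == 0.55
        assert str(worked_graph.graph.value(outcome, C2["unit"])) == "um"

    def test_compound_carries_both_unification_xrefs(self, worked_graph):
        comp = URIRef(DEFAULT_BASE + "compound5591")
        refs = {
            (str(worked_graph.graph.value(x, C2["DB"])),
             str(worked_graph.graph.value(x, C2["ID"])))
            for x in worked_graph.graph.objects(comp, C2["xref"])
        }
        assert ("PubChem", "5591") in refs
        assert ("ChEBI", "9753") in refs

    def test_publication_xref_reachable_from_interaction(self, worked_graph, schema):
        binding = schema.class_uri("ChemicalBindsProtein")
        (inode,) = worked_graph.graph.subjects(RDF.type, binding)
        (assay,) = worked_graph.graph.objects(inode, C2["evidence"])
        titles = [worked_graph.graph.value(x, C2["title"])
                  for x in worked_graph.graph.objects(assay, C2["xref"])
                  if (x, RDF.type, schema.class_uri("PublicationXref"))
                  in worked_graph.graph]
        assert [str(t) for t in titles if t] == ["Synthetic placeholder reference"]


class TestAnnotateBasics:
    def test_empty_record_list_yields_empty_graph(self, schema):
        g = annotate([], compound_mapping(), schema)
        assert len(g) == 0

    def test_minimal_entity_record_matches_hand_enumeration(self, schema):
        rec = SourceRecord("src", "5591", "entity",
                           {"cid": "5591", "label": "Troglitazone"})
        g = annotate([rec], compound_mapping(), schema)
        uri = URIRef(DEFAULT_BASE + "compound5591")
        digest = hashlib.sha1(
            "\x00".join([str(uri), "PubChem", "5591"]).encode()
        ).hexdigest()[:16]
        xref = URIRef(DEFAULT_BASE + "unifxref" + digest)
        expected = {
            (uri, RDF.type, schema.class_uri("SmallMolecule")),
            (uri, C2["CID"], Literal(5591, datatype=XSD.integer)),
            (uri, RDFS.label, Literal("Troglitazone")),
            (uri, C2["xref"], xref),
            (xref, RDF.type, schema.class_uri("UnificationXref")),
            (xref, C2["DB"], Literal("PubChem")),
            (xref, C2["ID"], Literal("5591")),
        }
        assert set(g.graph) == expected

    def test_most_specific_type_asserted_once(self, worked_graph):
        for node in set(worked_graph.graph.subjects(RDF.type, None)):
            assert len(worked_graph.asserted_types(node)) == 1

    def test_interaction_with_unresolvable_participant_skipped(self, schema):
        mapping = MappingTable(sources={
            "ints": SourceMapping(
                record_kind="interaction", id_column="row_id",
                interaction_class="DrugInducedSideEffect",
                columns={"drug": "Drug", "disease": "Disease"}),
        })
        rec = SourceRecord("ints", "r1", "interaction",
                           {"row_id": "r1", "drug": "DB123",
                            "disease": "completely unknown malady"})
        g = annotate([rec], mapping, schema, ResolutionContext())
        assert len(list(g.graph.subjects(
            RDF.type, schema.class_uri("DrugInducedSideEffect")))) == 0


class TestProvenance:
    def test_two_unification_xrefs(self, schema):
        g = annotate([SourceRecord("src", "1", "entity", {"cid": "10"})],
                     compound_mapping(), schema)
        uri = DEFAULT_BASE + "compound10"
        attach_provenance(g, uri, [XRef("PubChem", "10"), XRef("ChEBI", "99")])
        xrefs = set(g.graph.objects(URIRef(uri), C2["xref"]))
        assert len(xrefs) == 2

    def test_duplicate_db_id_pairs_collapse(self, schema):
        g = annotate([SourceRecord("src", "1", "entity", {"cid": "10"})],
                     compound_mapping(), schema)
        uri = DEFAULT_BASE + "compound10"
        attach_provenance(g, uri, [XRef("ChEBI", "99"), XRef("ChEBI", "99")])
        attach_provenance(g, uri, [XRef("ChEBI", "99")])
        xrefs = set(g.graph.objects(URIRef(uri), C2["xref"]))
        assert len(xrefs) == 2  # PubChem:10 from annotate + one ChEBI node

    def test_empty_xref_list_is_noop(self, schema):
        g = annotate([SourceRecord("src", "1", "entity", {"cid": "10"})],
                     compound_mapping(), schema)
        before = set(g.graph)
        attach_provenance(g, DEFAULT_BASE + "compound10", [])
        assert set(g.graph) == before

    def test_unknown_entity_raises(self, schema):
        g = annotate([], compound_mapping(), schema)
        with pytest.raises(GraphLookupError):
            attach_provenance(g, DEFAULT_BASE + "compound404", [XRef("x", "y")])

    def test_every_interaction_names_its_source(self, fixture_bundle, schema):
        _, _, graph = fixture_bundle
        from scb.ontology_schema import descendants
        inter_classes = {schema.class_uri(n)
                         for n in {"Interaction"} | descendants(schema, "Interaction")}
        nodes = {s for s, _, o in graph.graph.triples((None, RDF.type, None))
                 if o in inter_classes}
        assert nodes
        for node in nodes:
            dbs = {str(graph.graph.value(x, C2["DB"]))
                   for x in graph.graph.objects(node, C2["xref"])}
            assert dbs & {"bindmine", "chemreg", "drug_disease", "drug_sideeffect"}


class TestDeduplication:
    def test_same_batch_annotated_twice_is_idempotent(self, schema):
        recs = [SourceRecord("src", "1", "entity",
                             {"cid": "10", "label": "aspirin"})]
        g1 = deduplicate(annotate(recs, compound_mapping(), schema))
        g2 = deduplicate(annotate(recs + recs, compound_mapping(), schema))
        assert isomorphic(g1.graph, g2.graph)

    def test_cross_source_compound_records_merge(self, schema):
        mapping = MappingTable(sources={
            "a": SourceMapping(record_kind="entity", entity_kind="compound",
                               id_column="cid",
                               columns={"chebi": "xref:ChEBI"}),
            "b": SourceMapping(record_kind="entity", entity_kind="compound",
                               id_column="cid",
                               columns={"kegg": "xref:KEGG"}),
        })
        recs = [SourceRecord("a", "1", "entity", {"cid": "5591", "chebi": "9753"}),
                SourceRecord("b", "1", "entity", {"cid": "5591", "kegg": "C00001"})]
        g = deduplicate(annotate(recs, mapping, schema))
        comp_nodes = set(g.graph.subjects(RDF.type, schema.class_uri("SmallMolecule")))
        assert len(comp_nodes) == 1
        dbs = {str(g.graph.value(x, C2["DB"]))
               for x in g.graph.objects(comp_nodes.pop(), C2["xref"])}
        assert {"PubChem", "ChEBI", "KEGG"} <= dbs

    def test_parallel_interaction_entries_are_preserved(self, schema):
        mapping = MappingTable(sources={
            "s1": SourceMapping(record_kind="interaction", id_column="row_id",
                                interaction_class="ChemicalBindsProtein",
                                columns={"cid": "SmallMolecule", "prot": "Protein"}),
            "s2": SourceMapping(record_kind="interaction", id_column="row_id",
                                interaction_class="ChemicalBindsProtein",
                                columns={"c": "SmallMolecule", "p": "Protein"}),
        })
        recs = [
            SourceRecord("s1", "r1", "interaction",
                         {"row_id": "r1", "cid": "5591", "prot": "PPARG_HUMAN"}),
            SourceRecord("s2", "r9", "interaction",
                         {"row_id": "r9", "c": "5591", "p": "PPARG_HUMAN"}),
        ]
        g = deduplicate(annotate(recs, mapping, schema))
        inodes = set(g.graph.subjects(RDF.type, schema.class_uri("ChemicalBindsProtein")))
        assert len(inodes) == 2  # parallel entries kept as distinct nodes
        shared = [set(g.graph.objects(i, RO["has_participant"])) for i in inodes]
        assert shared[0] == shared[1]

    def test_round_trip_preserves_isomorphism(self, worked_graph):
        from scb.semgraph import SemanticGraph
        ttl = worked_graph.serialize("turtle")
        back = SemanticGraph.parse(ttl, "turtle")
        assert isomorphic(worked_graph.graph, back.graph)
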