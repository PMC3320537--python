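"""Query templates, SPARQL guardrails and the case-study operations."""

import random

import pandas as pd
import pytest

from scb.annotation import (MappingTable, ResolutionContext, SourceMapping,
                            SourceRecord, annotate)
from scb.entity_resolution import DiseaseTermTable, mint_uri
from scb.errors import GraphLookupError, SchemaLookupError, UnsupportedFeatureError
from scb.pipeline import annotate_directory
from scb.reasoning import materialize
from scb.semantic_query import (disease_genes, drug_targets, drug_targets_by_source,
                                interaction_evidence, ligands_by_activity,
                                rank_targets_by_shared_drugs, run_sparql)


class TestSparqlGuardrails:
    def test_syntax_error_reported(self, worked_graph):
        with pytest.raises(Exception, match="(?i)expected|parse"):
            run_sparql(worked_graph, "SELECT ?x WHERE { ?x ?y }")

    @pytest.mark.parametrize("query", [
        "SELECT ?s WHERE { ?s ?p ?o MINUS { ?s a ?o } }",
        "SELECT ?s WHERE { SERVICE <http://example.org/sparql> { ?s ?p ?o } }",
        "SELECT ?s WHERE { ?s <http://x/p>+ ?o }",
    ])
    def test_unsupported_constructs_refused(self, worked_graph, query):
        with pytest.raises(UnsupportedFeatureError):
            run_sparql(worked_graph, query)

    def test_supported_subset_runs(self, worked_graph):
        q = """
        SELECT DISTINCT ?s WHERE {
          { ?s a ?t } UNION { ?s ?p ?o }
          OPTIONAL { ?s ?q ?v }
          FILTER(BOUND(?s))
        } ORDER BY ?s
        """
        assert list(run_sparql(worked_graph, q))


class TestDrugTargets:
    def test_worked_example_single_target(self, worked_graph):
        assert drug_targets(worked_graph, "Troglitazone") == {"PPARG"}

    def test_unknown_label_returns_empty(self, worked_graph):
        assert drug_targets(worked_graph, "Nonexistol") == set()

    def test_ontology_query_equals_union_of_source_queries(self, fixture_bundle,
                                                           fixture_config):
        _, manifest, graph = fixture_bundle
        for i in range(fixture_config.n_drugs):
            label = f"Droxamib{i:02d}"
            combined = drug_targets_by_source(graph, label, "bindmine") | \
                drug_targets_by_source(graph, label, "chemreg")
            assert drug_targets(graph, label) == combined
            assert sorted(combined) == manifest["drug_targets"][label]

    def test_leaf_typed_interactions_found_via_root_query(self, schema):
        """Interactions asserted only at leaf classes must still answer the
        branch-level query — that is what materialization buys."""
        mapping = MappingTable(sources={
            "s": SourceMapping(record_kind="interaction", id_column="rid",
                               interaction_class="ChemicalIncreasesExpression",
                               columns={"cid": "SmallMolecule", "prot": "Protein"}),
        })
        recs = [SourceRecord("s", "r1", "interaction",
                             {"rid": "r1", "cid": "77", "prot": "ABCB11_HUMAN"})]
        g = annotate(recs, mapping, schema)
        from rdflib import Literal, URIRef
        from rdflib.namespace import RDFS
        g.add((URIRef(mint_uri("compound", "77")), RDFS.label, Literal("cpd77")))
        g.add((URIRef(mint_uri("protein", "ABCB11_HUMAN")), RDFS.label,
               Literal("ABCB11")))
        assert drug_targets(g, "cpd77") == set()  # not yet materialized
        materialize(g, schema)
        assert drug_targets(g, "cpd77") == {"ABCB11"}


class TestInteractionEvidence:
    def test_worked_example_one_row(self, worked_graph):
        rows = interaction_evidence(worked_graph, "Troglitazone", "PPARG")
        assert len(rows) == 1
        row = rows[0]
        assert (row["measurement"], row["relation"], row["value"], row["unit"]) == \
            ("EC50", "=", 0.55, "um")
        assert row["title"] == "Synthetic placeholder reference"

    def test_pair_without_evidence_is_empty(self, worked_graph):
        assert interaction_evidence(worked_graph, "Troglitazone", "NOPE") == []

    def test_three_assays_two_titled(self, schema):
        mapping = MappingTable(sources={
            "s": SourceMapping(
                record_kind="interaction", id_column="rid",
                interaction_class="ChemicalBindsProtein",
                columns={"cid": "SmallMolecule", "prot": "Protein",
                         "desc": "description", "meas": "measurement",
                         "rel": "relation", "val": "value", "unit": "unit",
                         "pmid": "pubmed_id", "title": "title"}),
        })
        rows = [
            {"rid": "r1", "cid": "9", "prot": "T1_HUMAN", "desc": "assay one",
             "meas": "IC50", "rel": "=", "val": "10", "unit": "nm",
             "pmid": "111", "title": "paper one"},
            {"rid": "r2", "cid": "9", "prot": "T1_HUMAN", "desc": "assay two",
             "meas": "Ki", "rel": "<=", "val": "5", "unit": "um",
             "pmid": "222", "title": "paper two"},
            {"rid": "r3", "cid": "9", "prot": "T1_HUMAN", "desc": "assay three",
             "meas": "Kd", "rel": "=", "val": "2", "unit": "nm",
             "pmid": "", "title": ""},
        ]
        recs = [SourceRecord("s", r["rid"], "interaction", r) for r in rows]
        g = annotate(recs, mapping, schema)
        from rdflib import Literal, URIRef
        from rdflib.namespace import RDFS
        g.add((URIRef(mint_uri("compound", "9")), RDFS.label, Literal("c9")))
        g.add((URIRef(mint_uri("protein", "T1_HUMAN")), RDFS.label, Literal("T1")))
        materialize(g, schema)
        got = interaction_evidence(g, "c9", "T1")
        assert len(got) == 3
        titled = [r for r in got if r["title"]]
        assert sorted(r["title"] for r in titled) == ["paper one", "paper two"]
        by_desc = {r["description"]: r for r in got}
        assert by_desc["assay two"]["relation"] == "<="


def _ligand_fixture(schema, weights):
    mapping = MappingTable(sources={
        "cpds": SourceMapping(record_kind="entity", entity_kind="compound",
                              id_column="cid",
                              columns={"label": "label", "smiles": "smiles",
                                       "weight": "molecularWeight"}),
        "ints": SourceMapping(record_kind="interaction", id_column="rid",
                              interaction_class="ReceptorAgonistActivity",
                              columns={"cid": "SmallMolecule", "prot": "Protein"}),
    })
    recs = []
    for i, w in enumerate(weights):
        cid = str(100 + i)
        recs.append(SourceRecord("cpds", cid, "entity",
                                 {"cid": cid, "label": f"L{i}", "smiles": f"C{i}CO",
                                  "weight": str(w)}))
        recs.append(SourceRecord("ints", f"r{i}", "interaction",
                                 {"rid": f"r{i}", "cid": cid, "prot": "NR1I2_HUMAN"}))
    g = annotate(recs, mapping, schema)
    from rdflib import Literal, URIRef
    from rdflib.namespace import RDFS
    g.add((URIRef(mint_uri("protein", "NR1I2_HUMAN")), RDFS.label, Literal("NR1I2")))
    materialize(g, schema)
    return g


class TestLigandsByActivity:
    def test_weight_filter_is_strict(self, schema):
        g = _ligand_fixture(schema, [450.0, 550.0, 500.0])
        hits = ligands_by_activity(g, "NR1I2", "ReceptorAgonistActivity", 500)
        uris = {u for u, _ in hits}
        assert uris == {mint_uri("compound", "100")}  # 450 only; 500.0 excluded
        assert {s for _, s in hits} == {"C0CO"}

    def test_zero_cutoff_empty(self, schema):
        g = _ligand_fixture(schema, [450.0])
        assert ligands_by_activity(g, "NR1I2", "ReceptorAgonistActivity", 0) == set()

    def test_branch_class_includes_leaf_instances(self, schema):
        g = _ligand_fixture(schema, [450.0])
        hits = ligands_by_activity(g, "NR1I2", "ChemicalBindsProtein", 500)
        assert len(hits) == 1

    def test_unknown_activity_class_raises(self, schema):
        g = _ligand_fixture(schema, [450.0])
        with pytest.raises(SchemaLookupError):
            ligands_by_activity(g, "NR1I2", "Frobnication", 500)
        with pytest.raises(SchemaLookupError):
            ligands_by_activity(g, "NR1I2", "DrugTreatment", 500)


def _disease_fixture(schema, tree, genes, texts=()):
    """tree: {doid: parent}; genes: {doid: [entry, ...]}."""
    mapping = MappingTable(sources={
        "do_terms": SourceMapping(record_kind="entity", entity_kind="disease",
                                  id_column="doid",
                                  columns={"label": "label",
                                           "parent": "disease_parent"}),
        "dg": SourceMapping(record_kind="entity", entity_kind="disease",
                            id_column="doid", columns={"gene": "disease_gene"}),
    })
    recs = []
    for doid, parent in tree.items():
        recs.append(SourceRecord("do_terms", doid, "entity",
                                 {"doid": doid, "label": f"name {doid}",
                                  "parent": parent or ""}))
    for doid, entries in genes.items():
        for e in entries:
            recs.append(SourceRecord("dg", doid, "entity",
                                     {"doid": doid, "gene": e}))
    g = annotate(recs, mapping, schema)
    materialize(g, schema)
    return g


class TestDiseaseGenes:
    def test_subtype_expansion_reaches_descendant_genes(self, schema):
        g = _disease_fixture(schema,
                             {"DOID:1": None, "DOID:2": "DOID:1"},
                             {"DOID:2": ["ABCB11_HUMAN"]})
        assert disease_genes(g, "DOID:1", expand=True) == \
            {mint_uri("protein", "ABCB11_HUMAN")}

    def test_without_expansion_no_direct_link(self, schema):
        g = _disease_fixture(schema,
                             {"DOID:1": None, "DOID:2": "DOID:1"},
                             {"DOID:2": ["ABCB11_HUMAN"]})
        assert disease_genes(g, "DOID:1", expand=False) == set()

    def test_lookup_by_label(self, schema):
        g = _disease_fixture(schema, {"DOID:1": None}, {"DOID:1": ["X_HUMAN"]})
        assert disease_genes(g, "name DOID:1", expand=False) == \
            {mint_uri("protein", "X_HUMAN")}

    def test_unknown_term_raises(self, schema):
        g = _disease_fixture(schema, {"DOID:1": None}, {})
        with pytest.raises(GraphLookupError):
            disease_genes(g, "DOID:404")

    @pytest.mark.parametrize("seed", range(10))
    def test_random_tree_equals_dfs_union_oracle(self, schema, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 12)
        doids = [f"DOID:{i}" for i in range(n)]
        tree = {doids[0]: None}
        for i in range(1, n):
            tree[doids[i]] = doids[rng.randrange(i)]
        genes = {d: [f"G{rng.randrange(20)}_HUMAN" for _ in range(rng.randrange(3))]
                 for d in doids}
        g = _disease_fixture(schema, tree, genes)
        # oracle: explicit DFS union over the child lists
        children = {}
        for d, p in tree.items():
            if p:
                children.setdefault(p, []).append(d)
        root = doids[rng.randrange(n)]
        stack, want = [root], set()
        while stack:
            d = stack.pop()
            want |= {mint_uri("protein", e) for e in genes.get(d, [])}
            stack.extend(children.get(d, []))
        assert disease_genes(g, root, expand=True) == want


class TestTargetRanking:
    def test_explicit_three_drug_scenario(self, fixture_bundle, schema):
        _, manifest, graph = fixture_bundle
        for doid, expected in manifest["target_rankings"].items():
            got = [[r.label, r.shared_drug_count]
                   for r in rank_targets_by_shared_drugs(graph, doid)]
            assert got == expected

    def test_counts_match_tsv_brute_force(self, fixture_bundle, schema):
        """Independent recount straight from the emitted tables."""
        outdir, manifest, graph = fixture_bundle
        drugs = pd.read_csv(outdir / "drugs.tsv", sep="\t", dtype=str)
        dd = pd.read_csv(outdir / "drug_disease.tsv", sep="\t", dtype=str)
        do = pd.read_csv(outdir / "do_terms.tsv", sep="\t", dtype=str,
                         keep_default_na=False)
        bind = pd.read_csv(outdir / "bindmine.tsv", sep="\t", dtype=str)
        chem = pd.read_csv(outdir / "chemreg.tsv", sep="\t", dtype=str)
        comps = pd.read_csv(outdir / "compounds.tsv", sep="\t", dtype=str,
                            keep_default_na=False)
        prots = pd.read_csv(outdir / "proteins.tsv", sep="\t", dtype=str)

        text_to_doid = {}
        for _, r in do.iterrows():
            text_to_doid[r["label"]] = r["doid"]
            for s in r["synonyms"].split("|"):
                if s:
                    text_to_doid[s] = r["doid"]
        children = {}
        for _, r in do.iterrows():
            if r["parent"]:
                children.setdefault(r["parent"], []).append(r["doid"])
        inchi_to_cid = dict(zip(comps["inchi"], comps["cid"]))
        gene_label = dict(zip(prots["entry_name"], prots["label"]))
        cid_targets = {}
        for _, r in bind.iterrows():
            cid_targets.setdefault(r["cid"], set()).add(gene_label[r["uniprot"]])
        for _, r in chem.iterrows():
            cid = inchi_to_cid.get(r["inchi"], "")
            if cid:
                cid_targets.setdefault(cid, set()).add(
                    gene_label[r["gene"].upper()])
        drug_cid = dict(zip(drugs["drugbank_id"], drugs["cid"]))

        doid = do.iloc[0]["doid"]  # the tree root covers every disease link
        dset, stack = {doid}, list(children.get(doid, []))
        while stack:
            d = stack.pop()
            dset.add(d)
            stack.extend(children.get(d, []))
        counts = {}
        for _, r in dd.iterrows():
            if text_to_doid[r["disease_text"]] in dset:
                for t in cid_targets.get(drug_cid[r["drugbank_id"]], set()):
                    counts.setdefault(t, set()).add(r["drugbank_id"])
        expected = sorted(((t, len(ds)) for t, ds in counts.items()),
                          key=lambda kv: (-kv[1], kv[0]))
        got = [(r.label, r.shared_drug_count)
               for r in rank_targets_by_shared_drugs(graph, doid)]
        assert got == expected
        assert got  # non-degenerate: the fixture links drugs to the root tree

    def test_no_linked_drugs_empty(self, schema):
        g = _disease_fixture(schema, {"DOID:1": None}, {})
        assert rank_targets_by_shared_drugs(g, "DOID:1") == []


class TestOrderInvariance:
    def test_results_unaffected_by_record_shuffling(self, fixture_bundle,
                                                    fixture_config, schema):
        outdir, manifest, graph = fixture_bundle
        from scb.pipeline import build_context, load_mapping, load_records
        from scb.annotation import deduplicate
        mapping = load_mapping(outdir / "mapping.yaml")
        records = load_records(outdir, mapping)
        random.Random(0).shuffle(records)
        g2 = deduplicate(annotate(records, mapping, schema,
                                  build_context(outdir)))
        materialize(g2, schema)
        label = "Droxamib00"
        assert drug_targets(g2, label) == drug_targets(graph, label)
        assert set(g2.graph) == set(graph.graph)
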