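"""Deterministic synthetic source tables with a ground-truth manifest.

The generator emulates the *shape* of public chemogenomics dumps — a
PubChem-like compound table that is authoritative for CIDs, two interaction
sources with different column vocabularies (a BindingDB-like assay table
keyed by CID and a CTD-like table keyed by InChI), DrugBank-like drugs,
UniProt-like proteins with GO annotations, a SIDER-like drug–side-effect
table, a miniature disease-ontology tree with synonyms, disease–gene links
and precomputed compound-similarity pairs — not real chemistry or real
scale.  A configurable fraction of compounds lack both a CID and an InChI
hit in the offline lookup, so all three compound-resolution branches
(explicit CID, InChI lookup, surrogate minting) are exercised, and the two
interaction sources overlap on compounds so cross-source merging always
occurs.

``manifest.json`` records ground truth recomputed by brute force from the
emitted tables: per-drug target sets (overall and per source), expanded
disease→gene sets, per-pair evidence counts and the bounded simple-path set
for one designated node pair.  Node identifiers in the manifest are
package-independent canonical ids (``compound:<cid>``, ``protein:<entry>``,
``drug:<id>``, ``disease:<doid>``, ``go:<goid>``, ``sideeffect:<umls>``;
surrogate compounds appear as ``compound:inchi=<inchi>``).

All numeric assay outcomes are synthetic placeholders; none is a real
measurement.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["FixtureConfig", "generate", "worked_example", "figure6_example"]

GO_POOL = ["GO:0003707", "GO:0004985", "GO:0005249", "GO:0005515",
           "GO:0006810", "GO:0008152", "GO:0016020", "GO:0055085"]

#: action term → interaction class, per source vocabulary
BINDMINE_ACTIONS = {
    "binding": "ChemicalBindsProtein",
    "agonist": "ReceptorAgonistActivity",
    "antagonist": "ReceptorAntagonistActivity",
    "inhibition": "ChemicalInhibitsProtein",
    "activation": "ChemicalActivatesProtein",
}
CHEMREG_ACTIONS = {
    "increases^expression": "ChemicalIncreasesExpression",
    "decreases^expression": "ChemicalDecreasesExpression",
    "metabolism": "ProteinMetabolizesChemical",
    "transport": "ProteinTransportsChemical",
    "binds": "ChemicalBindsProtein",
}

MEASUREMENTS = ["EC50", "IC50", "Ki", "Kd"]
RELATIONS = ["=", "<=", ">="]
UNITS = ["um", "nm"]

SIMILARITY_THRESHOLD = 0.85  # manifest paths assume this overlay cutoff
DESIGNATED_MAX_LEN = 2


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the synthetic study conditions."""

    seed: int = 42
    n_compounds: int = 60
    n_drugs: int = 12
    n_proteins: int = 15
    n_interactions: int = 120
    n_sources: int = 2
    n_diseases: int = 10
    n_side_effects: int = 6
    surrogate_fraction: float = 0.15

    def validate(self) -> None:
        for name in ("n_compounds", "n_drugs", "n_proteins", "n_interactions",
                     "n_sources", "n_diseases", "n_side_effects"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.surrogate_fraction <= 1.0:
            raise ValidationError("surrogate_fraction must lie in [0, 1]")
        n_real = self.n_compounds - round(self.surrogate_fraction * self.n_compounds)
        if self.n_drugs > n_real:
            raise ValidationError("n_drugs exceeds the number of CID-bearing compounds")
        if not 1 <= self.n_sources <= 2:
            raise ValidationError("n_sources must be 1 or 2")


def _write(path: Path, header: list[str], rows: list[list]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join("" if v is None else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _mapping_yaml(n_sources: int) -> dict:
    sources = {
        "compounds": {
            "record_kind": "entity", "entity_kind": "compound", "id_column": "cid",
            "columns": {"label": "label", "inchi": "inchi", "smiles": "smiles",
                        "weight": "molecularWeight", "chebi": "xref:ChEBI"},
        },
        "drugs": {
            "record_kind": "entity", "entity_kind": "drug", "id_column": "drugbank_id",
            "columns": {"label": "label", "cid": "xref:PubChem"},
        },
        "proteins": {
            "record_kind": "entity", "entity_kind": "protein", "id_column": "entry_name",
            "columns": {"label": "label", "go_terms": "go_terms"},
        },
        "do_terms": {
            "record_kind": "entity", "entity_kind": "disease", "id_column": "doid",
            "columns": {"label": "label", "synonyms": "synonyms",
                        "parent": "disease_parent"},
        },
        "disease_genes": {
            "record_kind": "entity", "entity_kind": "disease", "id_column": "doid",
            "columns": {"gene": "disease_gene"},
        },
        "bindmine": {
            "record_kind": "interaction", "id_column": "row_id",
            "interaction_class": "ChemicalProteinInteraction",
            "columns": {"cid": "SmallMolecule", "uniprot": "Protein",
                        "action": "interaction_type", "measurement": "measurement",
                        "relation": "relation", "value": "value", "unit": "unit",
                        "assay_desc": "description", "pmid": "pubmed_id",
                        "title": "title"},
            "value_maps": {"action": dict(BINDMINE_ACTIONS)},
        },
        "drug_disease": {
            "record_kind": "interaction", "id_column": "row_id",
            "interaction_class": "DrugInducedSideEffect",
            "columns": {"drugbank_id": "Drug", "disease_text": "Disease"},
        },
        "drug_sideeffect": {
            "record_kind": "interaction", "id_column": "row_id",
            "interaction_class": "DrugInducedSideEffect",
            "columns": {"drugbank_id": "Drug", "umls": "SideEffect"},
        },
    }
    if n_sources >= 2:
        sources["chemreg"] = {
            "record_kind": "interaction", "id_column": "row_id",
            "interaction_class": "ChemicalProteinInteraction",
            "columns": {"inchi": "inchi", "gene": "Protein",
                        "act_type": "interaction_type", "pubmed": "pubmed_id"},
            "value_maps": {"act_type": dict(CHEMREG_ACTIONS)},
        }
    return {"sources": sources}


def generate(config: FixtureConfig, outdir) -> tuple[Path, dict]:
    """Emit source TSVs + ``mapping.yaml`` + ``manifest.json`` into ``outdir``.

    Byte-identical for identical configs; returns (outdir, manifest).
    """
    config.validate()
    rng = random.Random(config.seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    n_sur = round(config.surrogate_fraction * config.n_compounds)
    n_real = config.n_compounds - n_sur

    # --- compounds --------------------------------------------------------
    compounds = []
    for i in range(config.n_compounds):
        cid = 5000 + i if i < n_real else None
        label = f"Droxamib{i:02d}" if i < config.n_drugs else f"CPD-{i:04d}"
        inchi = f"InChI=1S/C{10 + i}H{12 + i}N{1 + i % 3}O{2 + i % 4}/synthetic{i:04d}"
        smiles = "C" * (3 + i % 5) + "N" * (1 + i % 2) + f"(=O)c{i % 9}"
        weight = round(rng.uniform(150.0, 700.0), 1)
        chebi = 20000 + i if rng.random() < 0.5 else None
        compounds.append({"cid": cid, "label": label, "inchi": inchi,
                          "smiles": smiles, "weight": weight, "chebi": chebi})
    _write(out / "compounds.tsv",
           ["cid", "label", "inchi", "smiles", "weight", "chebi"],
           [[c["cid"], c["label"], c["inchi"], c["smiles"],
             f"{c['weight']:.1f}", c["chebi"]] for c in compounds])
    _write(out / "inchi_cid.tsv", ["inchi", "cid"],
           [[c["inchi"], c["cid"]] for c in compounds if c["cid"] is not None])

    def ckey(c) -> str:
        return (f"compound:{c['cid']}" if c["cid"] is not None
                else f"compound:inchi={c['inchi']}")

    # --- drugs / proteins -------------------------------------------------
    drugs = [{"drugbank_id": f"DB{10000 + i}", "label": compounds[i]["label"],
              "cid": compounds[i]["cid"], "compound": i}
             for i in range(config.n_drugs)]
    _write(out / "drugs.tsv", ["drugbank_id", "label", "cid"],
           [[d["drugbank_id"], d["label"], d["cid"]] for d in drugs])

    proteins = []
    for i in range(config.n_proteins):
        gos = sorted(rng.sample(GO_POOL, rng.randint(1, 3)))
        proteins.append({"entry": f"PR{i:02d}A_HUMAN", "label": f"GN{i:02d}",
                         "go": gos})
    _write(out / "proteins.tsv", ["entry_name", "label", "go_terms"],
           [[p["entry"], p["label"], "|".join(p["go"])] for p in proteins])

    # --- disease tree -----------------------------------------------------
    diseases = []
    for i in range(config.n_diseases):
        doid = f"DOID:{9000 + i}"
        parent = diseases[rng.randrange(max(0, i - 5), i)]["doid"] if i >= 2 else (
            diseases[0]["doid"] if i == 1 else None)
        diseases.append({"doid": doid, "label": f"disorder {i:02d}",
                         "synonyms": [f"condition {i:02d}", f"syndrome {i:02d}"],
                         "parent": parent})
    _write(out / "do_terms.tsv", ["doid", "label", "synonyms", "parent"],
           [[d["doid"], d["label"], "|".join(d["synonyms"]), d["parent"]]
            for d in diseases])

    # --- chemical-protein interactions, two source schemas ----------------
    bindmine_rows, chemreg_rows = [], []
    interactions = []  # (ckey, protein idx, class, source)
    for i in range(config.n_interactions):
        if rng.random() < 0.5 and config.n_drugs:
            c = rng.randrange(config.n_drugs)
        else:
            c = rng.randrange(config.n_compounds)
        p = rng.randrange(config.n_proteins)
        comp = compounds[c]
        use_chemreg = config.n_sources >= 2 and (
            comp["cid"] is None or rng.random() < 0.45)
        if use_chemreg:
            act = rng.choice(sorted(CHEMREG_ACTIONS))
            pubmed = 20000000 + rng.randrange(100000) if rng.random() < 0.3 else None
            chemreg_rows.append([f"cr{i:04d}", comp["inchi"],
                                 proteins[p]["entry"].lower(), act, pubmed])
            interactions.append((ckey(comp), p, CHEMREG_ACTIONS[act], "chemreg"))
        else:
            act = rng.choice(sorted(BINDMINE_ACTIONS))
            meas = rng.choice(MEASUREMENTS)
            rel = rng.choice(RELATIONS)
            val = round(rng.uniform(0.01, 900.0), 2)
            unit = rng.choice(UNITS)
            pmid = 10000000 + rng.randrange(100000) if rng.random() < 0.6 else None
            title = f"Synthetic assay report {i:04d}" if pmid else None
            bindmine_rows.append([f"bm{i:04d}", comp["cid"], proteins[p]["entry"],
                                  act, meas, rel, f"{val:.2f}", unit,
                                  f"{meas} assay of {comp['label']} vs {proteins[p]['label']}",
                                  pmid, title])
            interactions.append((ckey(comp), p, BINDMINE_ACTIONS[act], "bindmine"))
    _write(out / "bindmine.tsv",
           ["row_id", "cid", "uniprot", "action", "measurement", "relation",
            "value", "unit", "assay_desc", "pmid", "title"], bindmine_rows)
    if config.n_sources >= 2:
        _write(out / "chemreg.tsv",
               ["row_id", "inchi", "gene", "act_type", "pubmed"], chemreg_rows)

    # --- drug–disease / drug–side-effect / disease–gene -------------------
    dd_rows, links_dd = [], []
    for j, d in enumerate(drugs):
        for k in range(rng.randint(1, 2) if config.n_diseases else 0):
            dis = diseases[rng.randrange(config.n_diseases)]
            text = rng.choice([dis["label"]] + dis["synonyms"])
            dd_rows.append([f"dd{j:03d}_{k}", d["drugbank_id"], text])
            links_dd.append((d["drugbank_id"], dis["doid"]))
    _write(out / "drug_disease.tsv", ["row_id", "drugbank_id", "disease_text"], dd_rows)

    se_rows = []
    for j, d in enumerate(drugs):
        if config.n_side_effects and rng.random() < 0.7:
            se = rng.randrange(config.n_side_effects)
            se_rows.append([f"se{j:03d}", d["drugbank_id"], f"C{1000000 + se}"])
    _write(out / "drug_sideeffect.tsv", ["row_id", "drugbank_id", "umls"], se_rows)

    dg_rows, links_dg = [], []
    for d in diseases:
        for p in sorted(rng.sample(range(config.n_proteins),
                                   rng.randint(0, min(2, config.n_proteins)))):
            dg_rows.append([d["doid"], proteins[p]["entry"]])
            links_dg.append((d["doid"], p))
    _write(out / "disease_genes.tsv", ["doid", "gene"], dg_rows)

    # --- similarity pairs -------------------------------------------------
    sim_rows = []
    real = [c for c in compounds if c["cid"] is not None]
    for _ in range(2 * max(1, config.n_drugs)):
        a, b = rng.sample(range(len(real)), 2)
        score = round(rng.uniform(0.3, 1.0), 2)
        sim_rows.append([real[a]["cid"], real[b]["cid"], f"{score:.2f}"])
    _write(out / "similarity.tsv", ["cid_a", "cid_b", "score"], sim_rows)

    (out / "mapping.yaml").write_text(
        yaml.safe_dump(_mapping_yaml(config.n_sources), sort_keys=True))

    manifest = _build_manifest(config, compounds, drugs, proteins, diseases,
                               interactions, links_dd, links_dg, sim_rows)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out, manifest


# ---------------------------------------------------------------------------
# Ground truth, brute-forced from the in-memory row sets
# ---------------------------------------------------------------------------

def _build_manifest(config, compounds, drugs, proteins, diseases,
                    interactions, links_dd, links_dg, sim_rows) -> dict:
    def ckey(c):
        return (f"compound:{c['cid']}" if c["cid"] is not None
                else f"compound:inchi={c['inchi']}")

    label_of = {ckey(c): c["label"] for c in compounds}

    drug_targets: dict[str, set] = {c["label"]: set() for c in compounds}
    per_source: dict[str, dict[str, set]] = {
        c["label"]: {"bindmine": set(), "chemreg": set()} for c in compounds}
    evidence: dict[str, int] = {}
    for key, p, cls, source in interactions:
        label = label_of[key]
        gene = proteins[p]["label"]
        drug_targets[label].add(gene)
        per_source[label][source].add(gene)
        if source == "bindmine":  # every bindmine row carries one assay
            evidence[f"{label}|{gene}"] = evidence.get(f"{label}|{gene}", 0) + 1

    children: dict[str, list[str]] = {}
    for d in diseases:
        if d["parent"]:
            children.setdefault(d["parent"], []).append(d["doid"])
    direct_genes: dict[str, set] = {d["doid"]: set() for d in diseases}
    for doid, p in links_dg:
        direct_genes[doid].add(proteins[p]["label"])

    def expanded(doid):
        out, stack = set(direct_genes[doid]), list(children.get(doid, []))
        while stack:
            d = stack.pop()
            out |= direct_genes[d]
            stack.extend(children.get(d, []))
        return out

    # Shared-drug target ranking per disease (expansion always on).
    def desc_set(doid):
        out, stack = {doid}, list(children.get(doid, []))
        while stack:
            d = stack.pop()
            out.add(d)
            stack.extend(children.get(d, []))
        return out

    drug_by_id = {d["drugbank_id"]: d for d in drugs}
    rankings = {}
    for d in diseases:
        dset = desc_set(d["doid"])
        linked = {db for db, doid in links_dd if doid in dset}
        target_drugs: dict[str, set] = {}
        for db in linked:
            comp = compounds[drug_by_id[db]["compound"]]
            for key, p, cls, source in interactions:
                if key == ckey(comp):
                    target_drugs.setdefault(proteins[p]["label"], set()).add(db)
        rankings[d["doid"]] = [
            [gene, len(dbs)]
            for gene, dbs in sorted(target_drugs.items(),
                                    key=lambda kv: (-len(kv[1]), kv[0]))
        ]

    # Bounded simple paths for one designated pair, over the canonical-id
    # association network (deduplicated undirected labeled edges).
    edges: set[tuple[str, str, str]] = set()

    def add_edge(a, b, label):
        if a != b:
            edges.add((min(a, b), max(a, b), label))

    for key, p, cls, _src in interactions:
        add_edge(key, f"protein:{proteins[p]['entry']}", cls)
    for db, doid in links_dd:
        add_edge(f"drug:{db}", f"disease:{doid}", "DrugInducedSideEffect")
    for doid, p in links_dg:
        add_edge(f"disease:{doid}", f"protein:{proteins[p]['entry']}",
                 "has_associated_gene")
    for d in diseases:
        if d["parent"]:
            add_edge(f"disease:{d['doid']}", f"disease:{d['parent']}",
                     "disease_subtype_of")
    for p in proteins:
        for go in p["go"]:
            add_edge(f"protein:{p['entry']}", f"go:{go}", "has_go_annotation")
    for a, b, score in sim_rows:
        if float(score) >= SIMILARITY_THRESHOLD:
            add_edge(f"compound:{a}", f"compound:{b}", "similar_to")

    adj: dict[str, list[tuple[str, str]]] = {}
    for a, b, label in edges:
        adj.setdefault(a, []).append((b, label))
        adj.setdefault(b, []).append((a, label))

    designated = None
    if drugs and proteins:
        start = f"compound:{compounds[drugs[0]['compound']]['cid']}"
        goal = f"protein:{proteins[0]['entry']}"
        paths = []

        def dfs(node, nodes, labels):
            if node == goal and labels:
                paths.append({"nodes": list(nodes), "edge_labels": list(labels)})
                return
            if len(labels) == DESIGNATED_MAX_LEN:
                return
            for nxt, label in sorted(adj.get(node, [])):
                if nxt not in nodes:
                    dfs(nxt, nodes + [nxt], labels + [label])

        dfs(start, [start], [])
        paths.sort(key=lambda p: (len(p["edge_labels"]), p["nodes"], p["edge_labels"]))
        designated = {"a": start, "b": goal, "max_len": DESIGNATED_MAX_LEN,
                      "similarity_threshold": SIMILARITY_THRESHOLD, "paths": paths}

    return {
        "config": asdict(config),
        "drug_targets": {k: sorted(v) for k, v in drug_targets.items()},
        "drug_targets_by_source": {
            k: {s: sorted(v) for s, v in sv.items()} for k, sv in per_source.items()},
        "disease_genes_expanded": {d["doid"]: sorted(expanded(d["doid"]))
                                   for d in diseases},
        "evidence_counts": evidence,
        "target_rankings": rankings,
        "designated_paths": designated,
        "row_counts": {"compounds": len(compounds), "drugs": len(drugs),
                       "proteins": len(proteins), "interactions": len(interactions),
                       "diseases": len(diseases)},
    }


# ---------------------------------------------------------------------------
# Hand-written worked examples
# ---------------------------------------------------------------------------

def worked_example(outdir) -> Path:
    """The Troglitazone (CID 5591) / PPARG binding scenario.

    One compound with PubChem and ChEBI cross-references, one protein, one
    binding interaction backed by a bioassay with an outcome quadruple and a
    publication reference.  Assay outcome values and the article reference
    are synthetic placeholders, not real measurements.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write(out / "compounds.tsv",
           ["cid", "label", "inchi", "smiles", "weight", "chebi"],
           [[5591, "Troglitazone", "InChI=1S/C24H27NO5S/synthetic-placeholder",
             "Cc1c(C)c2c(c(C)c1O)CCC(C)(COc1ccc(CC3SC(=O)NC3=O)cc1)O2",
             "441.5", 9753]])
    _write(out / "proteins.tsv", ["entry_name", "label", "go_terms"],
           [["PPARG_HUMAN", "PPARG", "GO:0003707"]])
    _write(out / "bindmine.tsv",
           ["row_id", "cid", "uniprot", "action", "measurement", "relation",
            "value", "unit", "assay_desc", "pmid", "title"],
           [["bm0001", 5591, "PPARG_HUMAN", "binding", "EC50", "=", "0.55",
             "um", "Reporter-gene binding assay of Troglitazone vs PPARG",
             "90000001", "Synthetic placeholder reference"]])
    _write(out / "inchi_cid.tsv", ["inchi", "cid"],
           [["InChI=1S/C24H27NO5S/synthetic-placeholder", 5591]])
    _write(out / "do_terms.tsv", ["doid", "label", "synonyms", "parent"], [])
    mapping = _mapping_yaml(n_sources=1)
    mapping["sources"] = {k: v for k, v in mapping["sources"].items()
                          if k in ("compounds", "proteins", "bindmine", "do_terms")}
    (out / "mapping.yaml").write_text(yaml.safe_dump(mapping, sort_keys=True))
    return out


def figure6_example(outdir) -> Path:
    """An indirect-association scenario: a query compound linked to a target
    it never directly binds, through (i) structurally similar compounds that
    bind it, (ii) a partner target sharing ligands with it, and (iii) shared
    GO annotations between the two targets.  CIDs echo the published example;
    everything else is synthetic.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    comps = [
        [44143441, "BZA-441", "InChI=1S/BZA441/synthetic", "c1ccc2[nH]cnc2c1CCN", "412.0", None],
        [44143442, "BZA-442", "InChI=1S/BZA442/synthetic", "c1ccc2[nH]cnc2c1CCO", "408.0", None],
        [44143438, "BZA-438", "InChI=1S/BZA438/synthetic", "c1ccc2[nH]cnc2c1CCC", "399.0", None],
        [44143439, "BZA-439", "InChI=1S/BZA439/synthetic", "c1ccc2[nH]cnc2c1CCF", "403.0", None],
        [777001, "SHR-001", "InChI=1S/SHR001/synthetic", "CCOc1ccccc1N", "310.0", None],
    ]
    _write(out / "compounds.tsv",
           ["cid", "label", "inchi", "smiles", "weight", "chebi"], comps)
    _write(out / "proteins.tsv", ["entry_name", "label", "go_terms"],
           [["KCNH2_HUMAN", "KCNH2", "GO:0005249|GO:0016020"],
            ["OPRL1_HUMAN", "OPRL1", "GO:0004985|GO:0016020"]])
    _write(out / "bindmine.tsv",
           ["row_id", "cid", "uniprot", "action", "measurement", "relation",
            "value", "unit", "assay_desc", "pmid", "title"],
           [["bm0001", 44143441, "OPRL1_HUMAN", "binding", "Ki", "=", "12.0",
             "nm", "Binding of BZA-441 vs OPRL1", None, None],
            ["bm0002", 44143442, "KCNH2_HUMAN", "binding", "IC50", "=", "210.0",
             "nm", "Binding of BZA-442 vs KCNH2", None, None],
            ["bm0003", 44143438, "KCNH2_HUMAN", "binding", "IC50", "=", "180.0",
             "nm", "Binding of BZA-438 vs KCNH2", None, None],
            ["bm0004", 44143439, "KCNH2_HUMAN", "binding", "IC50", "=", "95.0",
             "nm", "Binding of BZA-439 vs KCNH2", None, None],
            ["bm0005", 777001, "KCNH2_HUMAN", "binding", "IC50", "=", "50.0",
             "nm", "Binding of SHR-001 vs KCNH2", None, None],
            ["bm0006", 777001, "OPRL1_HUMAN", "binding", "Ki", "=", "8.0",
             "nm", "Binding of SHR-001 vs OPRL1", None, None]])
    _write(out / "similarity.tsv", ["cid_a", "cid_b", "score"],
           [[44143441, 44143442, "0.92"], [44143441, 44143438, "0.90"],
            [44143441, 44143439, "0.88"], [44143441, 777001, "0.40"]])
    _write(out / "inchi_cid.tsv", ["inchi", "cid"],
           [[c[2], c[0]] for c in comps])
    _write(out / "do_terms.tsv", ["doid", "label", "synonyms", "parent"], [])
    mapping = _mapping_yaml(n_sources=1)
    mapping["sources"] = {k: v for k, v in mapping["sources"].items()
                          if k in ("compounds", "proteins", "bindmine", "do_terms")}
    (out / "mapping.yaml").write_text(yaml.safe_dump(mapping, sort_keys=True))
    return out
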