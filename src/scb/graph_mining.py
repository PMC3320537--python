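"""Entity-graph construction and bounded simple-path mining.

The semantic graph is projected to a labeled entity network: interaction
nodes are contracted to edges between their participants (a clique for
multi-participant interactions), annotation links (protein → GO term,
disease → gene, disease subtype) keep their property names as labels, and
precomputed structural-similarity pairs can be overlaid as ``similar_to``
edges.  Path mining then enumerates all simple paths up to a length bound;
edges are treated as undirected associations, and parallel edges with
different labels yield distinct labeled paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
from rdflib import URIRef
from rdflib.namespace import RDF, RDFS

from .errors import GraphLookupError, ValidationError
from .namespaces import RO, core
from .ontology_schema import OntologySchema, descendants
from .semgraph import SemanticGraph

__all__ = ["EntityGraph", "PathResult", "build_entity_graph",
           "add_similarity_edges", "find_paths"]

#: Instance classes whose individuals become entity-graph nodes.
_ENTITY_CLASSES = ("SmallMolecule", "Drug", "Protein", "Disease",
                   "SideEffect", "Pathway", "GeneOntologyTerm")

#: Object properties projected as labeled annotation edges.
_ANNOTATION_EDGES = ("has_go_annotation", "has_associated_gene", "disease_subtype_of")


class EntityGraph(nx.MultiGraph):
    """Undirected labeled multigraph of entity instances.

    Node attribute ``cls`` holds the asserted class name; edge attribute
    ``label`` holds the interaction class, annotation property, or
    ``similar_to``.
    """


@dataclass(frozen=True)
class PathResult:
    """A simple path with its edge-label sequence."""

    nodes: tuple[str, ...]
    edge_labels: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.edge_labels)


def build_entity_graph(graph: SemanticGraph, schema: OntologySchema) -> EntityGraph:
    """Project the (materialized) semantic graph to an entity network.

    Utility nodes (xrefs, outcomes, structures, assays) and literals are
    excluded; interaction instances are contracted to edges labeled by their
    most specific asserted class.
    """
    c2 = core(schema.base)
    g = EntityGraph()

    uri_to_name = {str(schema.class_uri(n)): n for n in schema.classes}
    entity_classes = set(_ENTITY_CLASSES)
    for root in _ENTITY_CLASSES:
        entity_classes |= descendants(schema, root)

    def node_class(uri: URIRef) -> str | None:
        for t in graph.asserted_types(uri):
            name = uri_to_name.get(str(t))
            if name in entity_classes:
                return name
        return None

    # Entity nodes.
    for s, _, o in graph.triples((None, RDF.type, None)):
        name = uri_to_name.get(str(o))
        if name in entity_classes and (s, RDF.type, o) not in graph.inferred:
            label = graph.graph.value(s, RDFS.label)
            g.add_node(str(s), cls=name, label=str(label) if label else None)

    interaction_classes = {"Interaction"} | descendants(schema, "Interaction")

    # Contract interaction instances to participant edges.
    for inode in set(graph.graph.subjects(RO["has_participant"], None)):
        icls = None
        for t in graph.asserted_types(inode):
            name = uri_to_name.get(str(t))
            if name in interaction_classes:
                icls = name
                break
        if icls is None:
            continue
        parts = sorted(
            str(p) for p in graph.graph.objects(inode, RO["has_participant"])
            if node_class(p) is not None
        )
        for i, a in enumerate(parts):
            for b in parts[i + 1:]:
                if not g.has_edge(a, b, key=(icls, str(inode))):
                    g.add_edge(a, b, key=(icls, str(inode)), label=icls,
                               interaction=str(inode))

    # Annotation links keep their property name as edge label.
    for prop in _ANNOTATION_EDGES:
        p = c2[prop]
        for s, _, o in graph.triples((None, p, None)):
            if (s, p, o) in graph.inferred:
                continue
            if isinstance(o, URIRef) and str(s) in g and str(o) in g:
                if not g.has_edge(str(s), str(o), key=(prop, "")):
                    g.add_edge(str(s), str(o), key=(prop, ""), label=prop)
    return g


def add_similarity_edges(
    g: EntityGraph,
    pairs: Iterable[tuple[str, str, float]],
    threshold: float = 0.85,
) -> EntityGraph:
    """Overlay undirected ``similar_to`` edges for pairs scoring >= threshold.

    Scores outside [0, 1] raise ValidationError; endpoints absent from the
    graph are ignored (they carry no relations worth mining).
    """
    for a, b, score in pairs:
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValidationError(f"similarity score {score} outside [0, 1]")
        if score >= threshold and a in g and b in g and a != b:
            if not g.has_edge(a, b, key=("similar_to", "")):
                g.add_edge(a, b, key=("similar_to", ""), label="similar_to", score=score)
    return g


def find_paths(g: EntityGraph, a: str, b: str, max_len: int = 4) -> list[PathResult]:
    """All simple paths between ``a`` and ``b`` with at most ``max_len`` edges.

    Parallel edges produce one result per distinct label sequence.  Results
    are ordered by (length, node sequence, label sequence).
    """
    if a not in g:
        raise GraphLookupError(a)
    if b not in g:
        raise GraphLookupError(b)
    if max_len < 1:
        raise ValidationError("max_len must be >= 1")
    results = []
    for edge_path in nx.all_simple_edge_paths(g, a, b, cutoff=max_len):
        nodes = [a]
        labels = []
        for u, v, key in edge_path:
            nxt = v if u == nodes[-1] else u
            nodes.append(nxt)
            labels.append(g.edges[u, v, key]["label"])
        results.append(PathResult(tuple(nodes), tuple(labels)))
    # Parallel edges with identical labels (redundant database entries for
    # one pair) would yield repeated results; keep each labeled path once.
    return sorted(set(results), key=lambda p: (p.length, p.nodes, p.edge_labels))


def load_similarity_tsv(path) -> list[tuple[str, str, float]]:
    """Read ``cid_a<TAB>cid_b<TAB>score`` rows (compound URIs or raw CIDs)."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("cid_a\t"):
                continue
            a, b, score = line.split("\t")[:3]
            pairs.append((a, b, float(score)))
    return pairs
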