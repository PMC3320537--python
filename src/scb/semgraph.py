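"""In-memory semantic graph: an rdflib Graph plus inference bookkeeping.

Asserted and inferred triples live in one rdflib ``Graph`` (so SPARQL sees
both), with the inferred subset tracked separately so exports can include or
exclude materialized facts and so "most specific asserted type" stays
well-defined after reasoning.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable, Optional

from rdflib import Graph, URIRef
from rdflib.compare import isomorphic

from .errors import FormatError
from .namespaces import DEFAULT_NAMESPACES

if TYPE_CHECKING:  # pragma: no cover
    from .entity_resolution import XRef
    from .ontology_schema import OntologySchema

_FORMATS = {"turtle": "turtle", "ttl": "turtle", "rdfxml": "xml", "rdf/xml": "xml", "xml": "xml"}

Triple = tuple


class SemanticGraph:
    """A set of RDF triples with provenance and an asserted/inferred split."""

    def __init__(self, schema: Optional["OntologySchema"] = None):
        self.graph = Graph()
        self.inferred: set[Triple] = set()
        self.provenance: dict[str, list["XRef"]] = {}
        self.schema = schema
        self.materialized = False
        for prefix, uri in (schema.namespaces if schema else DEFAULT_NAMESPACES).items():
            self.graph.bind(prefix, uri)

    # -- mutation -----------------------------------------------------------
    def add(self, triple: Triple, inferred: bool = False) -> bool:
        """Add a triple; returns True if it was new.  Inferred never
        downgrades an asserted triple."""
        new = triple not in self.graph
        self.graph.add(triple)
        if inferred and new:
            self.inferred.add(triple)
        elif not inferred:
            self.inferred.discard(triple)
        return new

    def add_all(self, triples: Iterable[Triple], inferred: bool = False) -> int:
        return sum(self.add(t, inferred=inferred) for t in triples)

    # -- views --------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.graph)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.graph

    def triples(self, pattern=(None, None, None)):
        return self.graph.triples(pattern)

    def asserted_graph(self) -> Graph:
        g = Graph()
        for ns, uri in self.graph.namespaces():
            g.bind(ns, uri)
        for t in self.graph:
            if t not in self.inferred:
                g.add(t)
        return g

    def asserted_types(self, node: URIRef) -> set[URIRef]:
        from rdflib.namespace import RDF

        return {o for _, _, o in self.graph.triples((node, RDF.type, None))
                if (node, RDF.type, o) not in self.inferred}

    def has_node(self, uri: URIRef) -> bool:
        return next(self.graph.triples((uri, None, None)), None) is not None or \
            next(self.graph.triples((None, None, uri)), None) is not None

    # -- IO -----------------------------------------------------------------
    def serialize(self, format: str = "turtle", include_inferred: bool = True) -> str:
        fmt = _FORMATS.get(format.lower())
        if fmt is None:
            raise FormatError(f"unsupported format {format!r}; use 'turtle' or 'rdfxml'")
        g = self.graph if include_inferred else self.asserted_graph()
        return g.serialize(format=fmt)

    @classmethod
    def parse(cls, data_or_path, format: str = "turtle",
              schema: Optional["OntologySchema"] = None) -> "SemanticGraph":
        fmt = _FORMATS.get(format.lower())
        if fmt is None:
            raise FormatError(f"unsupported format {format!r}; use 'turtle' or 'rdfxml'")
        sg = cls(schema=schema)
        if isinstance(data_or_path, str) and "\n" not in data_or_path and \
                not data_or_path.lstrip().startswith(("@prefix", "<?xml", "<rdf")):
            sg.graph.parse(data_or_path, format=fmt)
        else:
            sg.graph.parse(data=data_or_path, format=fmt)
        return sg

    def isomorphic_to(self, other: "SemanticGraph") -> bool:
        return isomorphic(self.graph, other.graph)
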