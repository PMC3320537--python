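"""Forward-chaining materialization of schema entailments.

The rule set is RDFS-plus: subclass type propagation, subproperty
propagation, inverse completion, transitive closure, and domain/range
typing.  It is closed — no user-defined rules — and runs to a least
fixpoint, marking every new triple as inferred so asserted facts stay
distinguishable.  This profile covers every entailment the shipped query
templates rely on (an instance of a leaf interaction class is found by a
query over a branch or root class; ``has_participant`` edges answer
``participates_in`` patterns; disease-subtype chains expand transitively).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdflib import URIRef
from rdflib.namespace import RDF

from .ontology_schema import OntologySchema, ancestors
from .semgraph import SemanticGraph

logger = logging.getLogger(__name__)

__all__ = ["InferenceRuleSet", "materialize"]

RULES = (
    "type-propagation-via-subclass",
    "subproperty-propagation",
    "inverse-completion",
    "transitive-closure",
    "domain-range-typing",
)


@dataclass(frozen=True)
class InferenceRuleSet:
    """The fixed, documented rule set; exists for introspection only."""

    rules: tuple[str, ...] = field(default=RULES)


def _local_name(uri: URIRef, bases: tuple[str, ...]) -> str | None:
    s = str(uri)
    for b in bases:
        if s.startswith(b):
            return s[len(b):]
    return None


def materialize(graph: SemanticGraph, schema: OntologySchema) -> SemanticGraph:
    """Grow ``graph`` to the least fixpoint of the rule set, in place.

    Monotone (output ⊇ input) and idempotent; inferred triples carry the
    ``inferred`` flag.  Instances typed by a class the schema does not
    declare are warned about and left un-propagated.
    """
    from .namespaces import RO

    bases = (schema.base, str(RO))
    anc = {name: ancestors(schema, name) for name in schema.classes}
    class_uri = {name: schema.class_uri(name) for name in schema.classes}

    props = {}
    for p in schema.properties.values():
        if p.kind != "object-property":
            dom = class_uri[p.domain] if p.domain else None
            parent = str(schema.property_uri(p.parent)) if p.parent else None
            props[str(schema.property_uri(p.name))] = (None, False, dom, None, parent)
            continue
        props[str(schema.property_uri(p.name))] = (
            str(schema.property_uri(p.inverse)) if p.inverse else None,
            p.transitive,
            class_uri[p.domain] if p.domain else None,
            class_uri[p.range] if p.range else None,
            str(schema.property_uri(p.parent)) if p.parent else None,
        )

    warned: set[str] = set()
    changed = True
    while changed:
        changed = False
        new = []
        for s, p, o in graph.graph:
            if p == RDF.type and isinstance(o, URIRef):
                name = _local_name(o, bases)
                if name is None:
                    continue
                if name not in schema.classes:
                    if name not in warned and not name.startswith(
                        ("unifxref", "pubxref", "compound", "protein", "drug")
                    ):
                        warned.add(name)
                        logger.warning("instance typed by unknown class %r; not propagated", name)
                    continue
                for a in anc[name]:
                    new.append((s, RDF.type, class_uri[a]))
            elif str(p) in props:
                inv, trans, dom, rng, parent = props[str(p)]
                if inv and isinstance(o, URIRef):
                    new.append((o, URIRef(inv), s))
                if parent:
                    new.append((s, URIRef(parent), o))
                if dom is not None:
                    new.append((s, RDF.type, dom))
                if rng is not None and isinstance(o, URIRef):
                    new.append((o, RDF.type, rng))
                if trans:
                    for _, _, o2 in graph.graph.triples((o, p, None)):
                        if o2 != s:
                            new.append((s, p, o2))
        for t in new:
            if graph.add(t, inferred=True):
                changed = True
    graph.materialized = True
    return graph
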