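"""Shared RDF namespace handles.

The core vocabulary lives in a single hash namespace (``c2b2r`` by default);
BioPAX Level 3 and the OBO Relation Ontology are referenced, not imported,
so everything works offline.
"""

from rdflib import Namespace
from rdflib.namespace import OWL, RDF, RDFS, XSD  # noqa: F401  (re-exported)

DEFAULT_BASE = "http://chem2bio2rdf.org/chem2bio2owl#"

BIOPAX = Namespace("http://www.biopax.org/release/biopax-level3.owl#")
RO = Namespace("http://www.obofoundry.org/ro/ro.owl#")

DEFAULT_NAMESPACES = {
    "c2b2r": DEFAULT_BASE,
    "bp": str(BIOPAX),
    "ro": str(RO),
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "owl": str(OWL),
    "xsd": str(XSD),
}


def core(base: str = DEFAULT_BASE) -> Namespace:
    """Namespace object for the core vocabulary under ``base``."""
    return Namespace(base)
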