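"""Ontology schema for systems chemical biology.

Defines the class/property vocabulary used throughout the toolkit: nine
primary classes (SmallMolecule, Drug, Protein, BioAssay, Disease, SideEffect,
Literature, Pathway, Interaction), five Interaction subclasses, a 61-class
chemogenomic interaction hierarchy split into "chemical regulates protein"
and "protein regulates chemical" branches, and the utility classes that carry
structures, physical properties, assay outcomes and cross-reference
provenance.  The schema is a plain in-memory object; :func:`serialize_schema`
renders it as OWL (Turtle or RDF/XML) via rdflib.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import ConfigurationError, FormatError, SchemaLookupError
from .namespaces import BIOPAX, DEFAULT_NAMESPACES, RO, core

__all__ = [
    "OntologyClass",
    "PropertyDef",
    "OntologySchema",
    "build_schema",
    "descendants",
    "ancestors",
    "serialize_schema",
    "PRIMARY_CLASSES",
    "INTERACTION_SUBCLASSES",
    "CHEMOGENOMIC_HIERARCHY",
]

#: The nine primary classes.
PRIMARY_CLASSES = (
    "SmallMolecule",
    "Drug",
    "Protein",
    "BioAssay",
    "Disease",
    "SideEffect",
    "Literature",
    "Pathway",
    "Interaction",
)

#: The five direct subclasses of Interaction.
INTERACTION_SUBCLASSES = (
    "DrugInducedSideEffect",
    "DrugTreatment",
    "DrugDrugInteraction",
    "ProteinProteinInteraction",
    "ChemicalProteinInteraction",
)

# ---------------------------------------------------------------------------
# Chemogenomic interaction hierarchy.
#
# Canonical, versioned table of the 61 named classes strictly below
# ChemicalProteinInteraction.  Two branch roots partition the hierarchy by
# direction of action; the action vocabulary follows CTD-style interaction
# types (binding, activity/expression/abundance regulation, covalent
# modification, stability, folding, localization, cleavage, splicing,
# metabolism, conjugation, transport, catalysis) plus receptor agonist and
# antagonist activity.  Edit with care: the total must stay exactly 61.
# ---------------------------------------------------------------------------
CHEMOGENOMIC_HIERARCHY: Mapping[str, tuple[str, ...]] = {
    "ChemicalProteinInteraction": (
        "ChemicalRegulatesProtein",
        "ProteinRegulatesChemical",
    ),
    # --- branch 1: how chemicals act on proteins ---------------------------
    "ChemicalRegulatesProtein": (
        "ChemicalBindsProtein",
        "ChemicalRegulatesProteinActivity",
        "ChemicalRegulatesProteinExpression",
        "ChemicalRegulatesProteinAbundance",
        "ChemicalModifiesProtein",
        "ChemicalRegulatesProteinStability",
        "ChemicalRegulatesProteinFolding",
        "ChemicalRegulatesProteinLocalization",
        "ChemicalCleavesProtein",
        "ChemicalRegulatesProteinSplicing",
    ),
    "ChemicalBindsProtein": (
        "ReceptorAgonistActivity",
        "ReceptorAntagonistActivity",
        "AllostericModulation",
        "CovalentBinding",
    ),
    "ChemicalRegulatesProteinActivity": (
        "ChemicalActivatesProtein",
        "ChemicalInhibitsProtein",
    ),
    "ChemicalRegulatesProteinExpression": (
        "ChemicalIncreasesExpression",
        "ChemicalDecreasesExpression",
    ),
    "ChemicalRegulatesProteinAbundance": (
        "ChemicalIncreasesAbundance",
        "ChemicalDecreasesAbundance",
    ),
    "ChemicalModifiesProtein": (
        "ChemicalPhosphorylation",
        "ChemicalDephosphorylation",
        "ChemicalMethylation",
        "ChemicalDemethylation",
        "ChemicalAcetylation",
        "ChemicalDeacetylation",
        "ChemicalUbiquitination",
        "ChemicalSumoylation",
        "ChemicalGlycosylation",
        "ChemicalGlutathionylation",
        "ChemicalNitrosylation",
        "ChemicalOxidationOfProtein",
        "ChemicalReductionOfProtein",
        "ChemicalHydroxylation",
        "ChemicalADPRibosylation",
        "ChemicalLipidation",
    ),
    "ChemicalRegulatesProteinStability": (
        "ChemicalStabilizesProtein",
        "ChemicalDestabilizesProtein",
    ),
    "ChemicalRegulatesProteinLocalization": ("ChemicalRegulatesProteinSecretion",),
    # --- branch 2: how proteins act on chemicals ---------------------------
    "ProteinRegulatesChemical": (
        "ProteinMetabolizesChemical",
        "ProteinTransportsChemical",
        "ProteinCatalyzesChemicalReaction",
        "ProteinRegulatesChemicalAbundance",
        "ProteinBindsChemical",
    ),
    "ProteinMetabolizesChemical": (
        "ProteinOxidizesChemical",
        "ProteinReducesChemical",
        "ProteinHydrolyzesChemical",
        "ProteinDegradesChemical",
        "ProteinSynthesizesChemical",
        "ProteinActivatesProdrug",
        "ProteinConjugatesChemical",
    ),
    "ProteinConjugatesChemical": (
        "ChemicalGlucuronidation",
        "ChemicalSulfonation",
        "GlutathioneConjugation",
    ),
    "ProteinTransportsChemical": (
        "ProteinImportsChemical",
        "ProteinExportsChemical",
        "ProteinSecretesChemical",
    ),
    "ProteinRegulatesChemicalAbundance": (
        "ProteinIncreasesChemicalAbundance",
        "ProteinDecreasesChemicalAbundance",
    ),
}

#: Utility classes: modeling artifacts, deliberately outside PhysicalEntity.
UTILITY_CLASSES = (
    "ChemicalStructure",
    "UnificationXref",
    "PublicationXref",
    "BioAssayOutcome",
    "PhysicalProperty",
)


@dataclass(frozen=True)
class OntologyClass:
    """A named class with its parents and optional external-vocabulary mapping."""

    name: str
    parents: tuple[str, ...] = ()
    definition: str = ""
    external_mapping: Optional[tuple[str, str]] = None


@dataclass(frozen=True)
class PropertyDef:
    """An object or data property with domain/range and algebraic flags.

    ``parent`` declares rdfs:subPropertyOf for the subproperty-propagation
    inference rule; no core property uses it.
    """

    name: str
    kind: str  # "object-property" | "data-property"
    domain: Optional[str] = None
    range: Optional[str] = None
    inverse: Optional[str] = None
    transitive: bool = False
    parent: Optional[str] = None


@dataclass
class OntologySchema:
    """The full class/property schema plus namespace prefix map."""

    classes: dict[str, OntologyClass] = field(default_factory=dict)
    properties: dict[str, PropertyDef] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------
    @property
    def base(self) -> str:
        return self.namespaces["c2b2r"]

    def class_uri(self, name: str) -> URIRef:
        if name not in self.classes:
            raise SchemaLookupError(name)
        return core(self.base)[name]

    def property_uri(self, name: str) -> URIRef:
        if name not in self.properties:
            raise SchemaLookupError(name)
        prop = self.properties[name]
        ns = RO if name in ("participates_in", "has_participant") else core(self.base)
        del prop
        return ns[name]

    def has_class(self, name: str) -> bool:
        return name in self.classes

    def children(self, name: str) -> set[str]:
        if name not in self.classes:
            raise SchemaLookupError(name)
        return {c.name for c in self.classes.values() if name in c.parents}

    def subclass_pairs(self) -> Iterable[tuple[str, str]]:
        """Yield (child, parent) for every declared subclass axiom."""
        for cls in self.classes.values():
            for p in cls.parents:
                yield cls.name, p

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise ConfigurationError on failure."""
        for cls in self.classes.values():
            for p in cls.parents:
                if p not in self.classes:
                    raise ConfigurationError(
                        f"class {cls.name!r}: undeclared parent {p!r}"
                    )
        self._check_acyclic()
        for prop in self.properties.values():
            if prop.kind not in ("object-property", "data-property"):
                raise ConfigurationError(f"property {prop.name!r}: bad kind {prop.kind!r}")
            if prop.inverse is not None:
                if prop.kind != "object-property":
                    raise ConfigurationError(
                        f"data property {prop.name!r} must not declare an inverse"
                    )
                other = self.properties.get(prop.inverse)
                if other is None or other.inverse != prop.name:
                    raise ConfigurationError(
                        f"property {prop.name!r}: inverse {prop.inverse!r} is not "
                        "declared symmetrically"
                    )
        missing = [c for c in PRIMARY_CLASSES if c not in self.classes]
        if missing:
            raise ConfigurationError(f"missing primary classes: {missing}")
        for c in INTERACTION_SUBCLASSES:
            if "Interaction" not in self.classes[c].parents:
                raise ConfigurationError(f"{c} must be a direct subclass of Interaction")
        n = len(descendants(self, "ChemicalProteinInteraction"))
        if n != 61:
            raise ConfigurationError(
                f"chemogenomic hierarchy holds {n} classes, expected 61"
            )
        pe = descendants(self, "PhysicalEntity")
        for c in UTILITY_CLASSES:
            if c in pe:
                raise ConfigurationError(f"utility class {c} must not be a PhysicalEntity")

    def _check_acyclic(self) -> None:
        # Kahn topological sort over the subclass DAG.
        indeg = {name: 0 for name in self.classes}
        for child, _parent in self.subclass_pairs():
            indeg[child] += 1
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        children_of: dict[str, list[str]] = {n: [] for n in self.classes}
        for child, parent in self.subclass_pairs():
            children_of[parent].append(child)
        while queue:
            node = queue.pop()
            seen += 1
            for ch in children_of[node]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if seen != len(self.classes):
            raise ConfigurationError("subclass graph contains a cycle")


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

_EXTERNAL = {
    "SmallMolecule": ("BioPAX", "SmallMolecule"),
    "Protein": ("BioPAX", "Protein"),
    "Pathway": ("BioPAX", "Pathway"),
    "ChemicalStructure": ("BioPAX", "ChemicalStructure"),
    "UnificationXref": ("BioPAX", "UnificationXref"),
    "PublicationXref": ("BioPAX", "PublicationXref"),
    "Interaction": ("BioPAX", "Interaction"),
    "ChemicalPhosphorylation": ("GO", "GO:0016310"),
    "ProteinTransportsChemical": ("GO", "GO:0006810"),
}

_DEFINITIONS = {
    "SmallMolecule": "a small bioactive molecule",
    "Drug": "a chemical used in the treatment, cure, prevention or diagnosis of disease",
    "Protein": "a physical entity consisting of a sequence of amino acids",
    "BioAssay": "an experiment measuring the effect of a substance on a target or organism",
    "Disease": "a condition causing pain, dysfunction, distress or social problems",
    "SideEffect": "an undesired effect of a medicine",
    "Literature": "a scientific article",
    "Pathway": "a set or series of biological interactions (treated as a black box)",
    "Interaction": "a typed association between physical entities with optional evidence",
}


def build_schema(config: Optional[Mapping] = None) -> OntologySchema:
    """Build the full schema; deterministic, validated, offline.

    ``config`` may override namespace bases via ``{"namespaces": {"base": ...}}``.
    Unknown keys raise :class:`ConfigurationError` naming the key.
    """
    namespaces = dict(DEFAULT_NAMESPACES)
    if config:
        if not isinstance(config, Mapping):
            raise ConfigurationError("config must be a mapping")
        for key, value in config.items():
            if key != "namespaces":
                raise ConfigurationError(f"unknown config key {key!r}")
            if not isinstance(value, Mapping):
                raise ConfigurationError("config key 'namespaces' must be a mapping")
            for nk, nv in value.items():
                if nk == "base":
                    namespaces["c2b2r"] = str(nv)
                elif nk in namespaces:
                    namespaces[nk] = str(nv)
                else:
                    raise ConfigurationError(f"unknown config key 'namespaces.{nk}'")

    classes: dict[str, OntologyClass] = {}

    def add(name: str, *parents: str) -> None:
        classes[name] = OntologyClass(
            name=name,
            parents=tuple(parents),
            definition=_DEFINITIONS.get(name, ""),
            external_mapping=_EXTERNAL.get(name),
        )

    add("PhysicalEntity")
    add("SmallMolecule", "PhysicalEntity")
    add("Drug", "PhysicalEntity")
    add("Protein", "PhysicalEntity")
    add("Evidence")
    add("BioAssay", "Evidence")
    add("Literature", "Evidence")
    add("Disease")
    add("SideEffect")
    add("Pathway")
    add("GeneOntologyTerm")
    add("Interaction")
    for name in INTERACTION_SUBCLASSES:
        add(name, "Interaction")
    for parent, kids in CHEMOGENOMIC_HIERARCHY.items():
        for kid in kids:
            add(kid, parent)
    add("UtilityClass")
    for name in UTILITY_CLASSES:
        add(name, "UtilityClass")

    properties = {
        p.name: p
        for p in (
            PropertyDef("participates_in", "object-property",
                        domain=None, range="Interaction", inverse="has_participant"),
            PropertyDef("has_participant", "object-property",
                        domain="Interaction", range=None, inverse="participates_in"),
            PropertyDef("evidence", "object-property",
                        domain="Interaction", range="Evidence"),
            PropertyDef("xref", "object-property"),
            PropertyDef("hasOutcome", "object-property",
                        domain="BioAssay", range="BioAssayOutcome"),
            PropertyDef("structure", "object-property",
                        domain="SmallMolecule", range="ChemicalStructure"),
            PropertyDef("hasPhysicalProperty", "object-property",
                        domain=None, range="PhysicalProperty"),
            PropertyDef("has_go_annotation", "object-property",
                        domain="Protein", range="GeneOntologyTerm"),
            PropertyDef("has_associated_gene", "object-property",
                        domain="Disease", range="Protein"),
            PropertyDef("disease_subtype_of", "object-property",
                        domain="Disease", range="Disease", transitive=True),
            PropertyDef("DB", "data-property", domain=None, range="string"),
            PropertyDef("ID", "data-property", domain=None, range="string"),
            PropertyDef("comments", "data-property", domain=None, range="string"),
            PropertyDef("measurement", "data-property", domain="BioAssayOutcome", range="string"),
            PropertyDef("relation", "data-property", domain="BioAssayOutcome", range="string"),
            PropertyDef("value", "data-property", domain="BioAssayOutcome", range="decimal"),
            PropertyDef("unit", "data-property", domain="BioAssayOutcome", range="string"),
            PropertyDef("structureFormat", "data-property", domain="ChemicalStructure", range="string"),
            PropertyDef("structureData", "data-property", domain="ChemicalStructure", range="string"),
            PropertyDef("molecularWeight", "data-property", domain="PhysicalProperty", range="decimal"),
            PropertyDef("description", "data-property", domain="BioAssay", range="string"),
            PropertyDef("title", "data-property", domain=None, range="string"),
            PropertyDef("CID", "data-property", domain="SmallMolecule", range="integer"),
        )
    }

    schema = OntologySchema(classes=classes, properties=properties, namespaces=namespaces)
    schema.validate()
    return schema


# ---------------------------------------------------------------------------
# Queries over the schema
# ---------------------------------------------------------------------------

def descendants(schema: OntologySchema, name: str) -> set[str]:
    """Transitive subclass closure of ``name``, excluding ``name`` itself."""
    if name not in schema.classes:
        raise SchemaLookupError(name)
    out: set[str] = set()
    stack = [name]
    while stack:
        for child in schema.children(stack.pop()):
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


def ancestors(schema: OntologySchema, name: str) -> set[str]:
    """Transitive superclass closure of ``name``, excluding ``name`` itself."""
    if name not in schema.classes:
        raise SchemaLookupError(name)
    out: set[str] = set()
    stack = [name]
    while stack:
        for parent in schema.classes[stack.pop()].parents:
            if parent not in out:
                out.add(parent)
                stack.append(parent)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FORMATS = {"turtle": "turtle", "ttl": "turtle", "rdfxml": "xml", "rdf/xml": "xml", "xml": "xml"}


def schema_to_graph(schema: OntologySchema) -> Graph:
    """Render the schema as an rdflib OWL graph."""
    g = Graph()
    for prefix, uri in schema.namespaces.items():
        g.bind(prefix, uri)
    for cls in schema.classes.values():
        uri = schema.class_uri(cls.name)
        g.add((uri, RDF.type, OWL.Class))
        g.add((uri, RDFS.label, Literal(cls.name)))
        if cls.definition:
            g.add((uri, RDFS.comment, Literal(cls.definition)))
        if cls.external_mapping:
            vocab, term = cls.external_mapping
            g.add((uri, RDFS.seeAlso, Literal(f"{vocab}:{term}")))
        for p in cls.parents:
            g.add((uri, RDFS.subClassOf, schema.class_uri(p)))
    for prop in schema.properties.values():
        uri = schema.property_uri(prop.name)
        kind = OWL.ObjectProperty if prop.kind == "object-property" else OWL.DatatypeProperty
        g.add((uri, RDF.type, kind))
        if prop.domain:
            g.add((uri, RDFS.domain, schema.class_uri(prop.domain)))
        if prop.range and prop.kind == "object-property":
            g.add((uri, RDFS.range, schema.class_uri(prop.range)))
        elif prop.range:
            g.add((uri, RDFS.range, XSD[prop.range]))
        if prop.inverse:
            g.add((uri, OWL.inverseOf, schema.property_uri(prop.inverse)))
        if prop.transitive:
            g.add((uri, RDF.type, OWL.TransitiveProperty))
        if prop.parent:
            g.add((uri, RDFS.subPropertyOf, schema.property_uri(prop.parent)))
    return g


def serialize_schema(schema: OntologySchema, format: str = "turtle") -> str:
    """Serialize the schema as OWL in Turtle or RDF/XML."""
    fmt = _FORMATS.get(format.lower())
    if fmt is None:
        raise FormatError(f"unsupported format {format!r}; use 'turtle' or 'rdfxml'")
    return schema_to_graph(schema).serialize(format=fmt)


# Re-export for callers that want the BioPAX/RO handles alongside the schema.
BP = BIOPAX
OBO_RO = RO
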