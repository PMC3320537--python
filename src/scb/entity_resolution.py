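"""Identifier unification: primary IDs, stable URIs and xref provenance.

Each entity kind has one primary identifier namespace — PubChem CID for
compounds, DrugBank ID for drugs, UniProt entry name for proteins, UMLS ID
for side effects, Disease Ontology ID for diseases, the bare name for
pathways.  Compounds missing both a PubChem xref and an InChI hit in the
offline lookup get a *surrogate* CID: a negative integer minted
deterministically, rendered in URIs as ``compoundF<n>`` so fakes are visibly
distinct from real CIDs.

Disease free text is matched against a Disease Ontology term table in three
passes: exact DOID reference, normalized label/synonym equality, then
token-set Jaccard similarity with a configurable threshold (default 0.8,
ties broken by smallest DOID).
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence
from urllib.parse import quote

from .errors import AmbiguityError, ValidationError
from .namespaces import DEFAULT_BASE

logger = logging.getLogger(__name__)

__all__ = [
    "XRef",
    "ResolvedEntity",
    "CompoundLookup",
    "DiseaseTermTable",
    "CompoundResolver",
    "resolve_compound",
    "resolve_disease",
    "mint_uri",
    "URI_PREFIXES",
]

#: kind → URI local-name prefix; distinct prefixes keep minting injective.
URI_PREFIXES = {
    "compound": "compound",
    "drug": "drug",
    "protein": "protein",
    "disease": "disease",
    "side_effect": "sideeffect",
    "pathway": "pathway",
    "literature": "article",
    "bioassay": "bioassay",
    "interaction": "interaction",
    "go_term": "goterm",
}

_PUBCHEM_NAMES = {"pubchem", "pubchem compound", "pubchem_cid", "cid"}


@dataclass(frozen=True)
class XRef:
    """A (database, identifier) cross-reference with optional free-text comments."""

    DB: str
    ID: str
    comments: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.DB or not self.ID:
            raise ValidationError("XRef requires non-empty DB and ID")


@dataclass
class ResolvedEntity:
    """A source record unified to one primary identifier and URI."""

    kind: str
    primary_id: str
    uri: str
    is_surrogate: bool = False
    xrefs: list[XRef] = field(default_factory=list)


@dataclass
class CompoundLookup:
    """Offline InChI → CID table standing in for a structure search service."""

    inchi_to_cid: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for inchi, cid in self.inchi_to_cid.items():
            if int(cid) <= 0:
                raise ValidationError(f"CID for {inchi!r} must be a positive integer")

    @classmethod
    def from_tsv(cls, path) -> "CompoundLookup":
        table = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("inchi\t"):
                    continue
                inchi, cid = line.split("\t")[:2]
                table[inchi] = int(cid)
        return cls(table)


def mint_uri(kind: str, primary_id: str, base: str = DEFAULT_BASE) -> str:
    """Deterministic URI for (kind, primary_id); injective across kinds.

    Surrogate CIDs (negative integers) render as ``compoundF<n>``.
    Characters unsafe in a URI fragment are percent-encoded.
    """
    if not str(primary_id):
        raise ValidationError("primary_id must be non-empty")
    if kind not in URI_PREFIXES:
        raise ValidationError(f"unknown entity kind {kind!r}")
    pid = str(primary_id)
    if kind == "compound" and pid.lstrip("-").isdigit() and int(pid) < 0:
        pid = f"F{-int(pid)}"
    return base + URI_PREFIXES[kind] + quote(pid, safe="")


class CompoundResolver:
    """Resolve compound records to CIDs, minting surrogates deterministically.

    Surrogates are negative integers assigned in sorted order of the minting
    key (InChI when present, else the caller-supplied source key), so the
    same batch resolved twice — in any order — yields identical IDs.
    Call :meth:`assign_surrogates` with all unresolvable keys up front, or
    rely on first-come registration for incremental use.
    """

    def __init__(self, lookup: Optional[CompoundLookup] = None, base: str = DEFAULT_BASE):
        self.lookup = lookup or CompoundLookup()
        self.base = base
        self._surrogates: dict[str, int] = {}

    def assign_surrogates(self, keys: Iterable[str]) -> None:
        for key in sorted(set(keys) - set(self._surrogates)):
            self._surrogates[key] = -(len(self._surrogates) + 1)

    def _surrogate_for(self, key: str) -> int:
        if key not in self._surrogates:
            self._surrogates[key] = -(len(self._surrogates) + 1)
        return self._surrogates[key]

    def resolve(
        self,
        xrefs: Sequence[XRef] = (),
        inchi: Optional[str] = None,
        source_key: Optional[str] = None,
    ) -> ResolvedEntity:
        return resolve_compound(xrefs, inchi, self.lookup, base=self.base,
                                _registry=self, source_key=source_key)


def resolve_compound(
    xrefs: Sequence[XRef] = (),
    inchi: Optional[str] = None,
    lookup: Optional[CompoundLookup] = None,
    base: str = DEFAULT_BASE,
    _registry: Optional[CompoundResolver] = None,
    source_key: Optional[str] = None,
) -> ResolvedEntity:
    """Unify a compound record to a primary CID.

    Resolution order: explicit PubChem xref, then InChI hit in the offline
    lookup, then a deterministic surrogate CID.  Conflicting PubChem xrefs
    raise :class:`AmbiguityError`; all input xrefs are retained on the result.
    """
    if not xrefs and inchi is None:
        raise ValidationError("resolve_compound needs xrefs or an InChI")
    lookup = lookup or CompoundLookup()

    pubchem_ids = {x.ID for x in xrefs if x.DB.lower() in _PUBCHEM_NAMES}
    if len(pubchem_ids) > 1:
        raise AmbiguityError(
            f"conflicting PubChem xrefs: {sorted(pubchem_ids)}"
        )
    surrogate = False
    if pubchem_ids:
        cid = int(pubchem_ids.pop())
    elif inchi is not None and inchi in lookup.inchi_to_cid:
        cid = lookup.inchi_to_cid[inchi]
    else:
        key = inchi if inchi is not None else (source_key or "|".join(
            f"{x.DB}:{x.ID}" for x in sorted(xrefs, key=lambda x: (x.DB, x.ID))))
        registry = _registry or CompoundResolver(lookup, base)
        cid = registry._surrogate_for(key)
        surrogate = True
    return ResolvedEntity(
        kind="compound",
        primary_id=str(cid),
        uri=mint_uri("compound", str(cid), base),
        is_surrogate=surrogate,
        xrefs=list(xrefs),
    )


# ---------------------------------------------------------------------------
# Disease term matching
# ---------------------------------------------------------------------------

_PUNCT = re.compile(f"[{re.escape(string.punctuation)}]")


def _normalize(text: str) -> str:
    return _PUNCT.sub(" ", text.lower()).strip()


def _tokens(text: str) -> frozenset[str]:
    return frozenset(_normalize(text).split())


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


@dataclass
class DiseaseTermTable:
    """Disease Ontology terms: DOID, label, synonyms and parent DOID."""

    labels: dict[str, str] = field(default_factory=dict)          # doid → label
    synonyms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    parents: dict[str, Optional[str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "DiseaseTermTable":
        """Read ``doid<TAB>label<TAB>syn1|syn2<TAB>parent_doid`` rows."""
        table = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("doid\t"):
                    continue
                parts = (line.split("\t") + ["", "", ""])[:4]
                doid, label, syns, parent = parts
                table.labels[doid] = label
                table.synonyms[doid] = tuple(s for s in syns.split("|") if s)
                table.parents[doid] = parent or None
        return table

    def descendants(self, doid: str) -> set[str]:
        children: dict[str, list[str]] = {}
        for d, p in self.parents.items():
            if p:
                children.setdefault(p, []).append(d)
        out: set[str] = set()
        stack = [doid]
        while stack:
            for ch in children.get(stack.pop(), []):
                if ch not in out:
                    out.add(ch)
                    stack.append(ch)
        return out


def resolve_disease(
    term: str,
    do_terms: DiseaseTermTable,
    threshold: float = 0.8,
    base: str = DEFAULT_BASE,
) -> Optional[ResolvedEntity]:
    """Map a free-text disease term (or DOID) to a Disease Ontology entity.

    Match order: exact DOID, normalized-exact label or synonym, token-set
    Jaccard >= ``threshold`` (ties → lexicographically smallest DOID).
    Returns None — an unresolved-term signal, logged — when nothing matches.
    """
    term = term.strip()
    if term in do_terms.labels:
        return _disease_entity(term, do_terms, "exact-id", base)

    norm = _normalize(term)
    exact = sorted(
        doid for doid, label in do_terms.labels.items()
        if _normalize(label) == norm
        or any(_normalize(s) == norm for s in do_terms.synonyms.get(doid, ()))
    )
    if exact:
        return _disease_entity(exact[0], do_terms, "exact", base)

    q = _tokens(term)
    scored = []
    for doid, label in do_terms.labels.items():
        best = max(
            [_jaccard(q, _tokens(label))]
            + [_jaccard(q, _tokens(s)) for s in do_terms.synonyms.get(doid, ())]
        )
        if best >= threshold:
            scored.append((-best, doid))
    if scored:
        _, doid = min(scored)
        return _disease_entity(doid, do_terms, "token-set", base)

    logger.warning("disease term %r unresolved (threshold %.2f)", term, threshold)
    return None


def _disease_entity(doid: str, do_terms: DiseaseTermTable, method: str, base: str) -> ResolvedEntity:
    return ResolvedEntity(
        kind="disease",
        primary_id=doid,
        uri=mint_uri("disease", doid, base),
        xrefs=[XRef("DO", doid, comments=f"match-method: {method}")],
    )


def resolve_simple(kind: str, primary_id: str, base: str = DEFAULT_BASE,
                   xrefs: Sequence[XRef] = ()) -> ResolvedEntity:
    """Resolve kinds whose source ID is already primary (drug, protein, ...).

    Protein entry names are matched case-insensitively by uppercasing.
    """
    pid = str(primary_id).strip()
    if kind == "protein":
        pid = pid.upper()
    return ResolvedEntity(kind=kind, primary_id=pid, uri=mint_uri(kind, pid, base),
                          xrefs=list(xrefs))
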