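"""End-to-end convenience layer: directory of TSVs → materialized graph.

Reads a source directory produced by the fixtures module (or shaped like
one): one ``<source>.tsv`` per source declared in ``mapping.yaml``, plus the
offline ``inchi_cid.tsv`` compound lookup and the ``do_terms.tsv`` disease
term table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .annotation import MappingTable, ResolutionContext, SourceRecord, annotate, deduplicate
from .entity_resolution import CompoundLookup, CompoundResolver, DiseaseTermTable
from .namespaces import DEFAULT_BASE
from .ontology_schema import OntologySchema, build_schema
from .reasoning import materialize
from .semgraph import SemanticGraph

__all__ = ["load_mapping", "load_records", "build_context", "annotate_directory"]


def load_mapping(path) -> MappingTable:
    with open(path) as fh:
        return MappingTable.from_dict(yaml.safe_load(fh))


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_records(src_dir, mapping: MappingTable) -> list[SourceRecord]:
    """Rows of every mapped source table, entities before interactions."""
    src_dir = Path(src_dir)
    records: list[SourceRecord] = []
    ordered = sorted(mapping.sources.items(),
                     key=lambda kv: (kv[1].record_kind != "entity", kv[0]))
    for name, m in ordered:
        path = src_dir / f"{name}.tsv"
        if not path.exists():
            continue
        df = _read_tsv(path)
        for i, row in df.iterrows():
            fields = {c: str(v) for c, v in row.items()}
            rid = fields.get(m.id_column or "", "").strip() or f"r{i}"
            records.append(SourceRecord(source=name, record_id=rid,
                                        record_kind=m.record_kind, fields=fields))
    return records


def build_context(src_dir, base: str = DEFAULT_BASE,
                  disease_threshold: float = 0.8) -> ResolutionContext:
    src_dir = Path(src_dir)
    lookup_path = src_dir / "inchi_cid.tsv"
    lookup = CompoundLookup.from_tsv(lookup_path) if lookup_path.exists() else CompoundLookup()
    do_path = src_dir / "do_terms.tsv"
    do_terms = DiseaseTermTable.from_tsv(do_path) if do_path.exists() else DiseaseTermTable()
    return ResolutionContext(compounds=CompoundResolver(lookup, base),
                             do_terms=do_terms, disease_threshold=disease_threshold,
                             base=base)


def annotate_directory(
    src_dir,
    schema: Optional[OntologySchema] = None,
    reason: bool = True,
    base: str = DEFAULT_BASE,
    disease_threshold: float = 0.8,
) -> SemanticGraph:
    """Annotate every mapped table under ``src_dir``; optionally materialize."""
    schema = schema or build_schema()
    mapping = load_mapping(Path(src_dir) / "mapping.yaml")
    records = load_records(src_dir, mapping)
    ctx = build_context(src_dir, base=base, disease_threshold=disease_threshold)
    graph = deduplicate(annotate(records, mapping, schema, ctx))
    if reason:
        materialize(graph, schema)
    return graph
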