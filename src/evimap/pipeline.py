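"""Convenience wrappers chaining ingest → categorize → build → layout."""

from __future__ import annotations

from pathlib import Path

from .categorize import VerbLexicon, categorize_evidence, default_lexicon
from .ingest import CsvDialect, DEFAULT_DIALECT, IngestReport, read_entities, read_interactions
from .mapmodel import DiseaseMap, LayoutConfig, assign_layout, build_map


def build_map_from_csv(
    entities_path: str | Path,
    interactions_path: str | Path,
    lexicon: VerbLexicon | None = None,
    dialect: CsvDialect = DEFAULT_DIALECT,
    strict: bool = False,
    layout: LayoutConfig | None = LayoutConfig(),
    created: str | None = None,
) -> tuple[DiseaseMap, IngestReport]:
    """Run the full import pipeline on the two-CSV exchange format.

    Returns the (laid-out, unless ``layout=None``) disease map together
    with the combined ingest report.  Row-level problems are collected in
    the report; with ``strict`` they raise instead.
    """
    lexicon = lexicon or default_lexicon()
    entities, ent_report = read_entities(entities_path, dialect, strict)
    rows, int_report = read_interactions(interactions_path, entities, dialect, strict)
    report = IngestReport(
        n_entities=ent_report.n_entities,
        n_interaction_rows=int_report.n_interaction_rows,
        warnings=ent_report.warnings + int_report.warnings,
        errors=ent_report.errors + int_report.errors,
    )
    evidences = [(row, categorize_evidence(row, lexicon)) for row in rows]
    disease_map = build_map(
        entities,
        evidences,
        sources=[str(entities_path), str(interactions_path)],
        lexicon_name=lexicon.name,
        created=created,
    )
    if layout is not None:
        disease_map = assign_layout(disease_map, layout)
    return disease_map, report
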