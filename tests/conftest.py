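from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

import evimap as em

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

FIXED_CREATED = "2022-09-10T00:00:00+00:00"


@pytest.fixture
def lexicon() -> em.VerbLexicon:
    return em.default_lexicon()


def write_corpus(tmp_path: Path, config: em.SynthConfig):
    """Generate a corpus and write its two CSVs; returns paths + truth."""
    entities_csv, interactions_csv, truth = em.generate_corpus(config)
    e_path = tmp_path / "entities.csv"
    i_path = tmp_path / "interactions.csv"
    e_path.write_text(entities_csv, encoding="utf-8")
    i_path.write_text(interactions_csv, encoding="utf-8")
    return e_path, i_path, truth


def build_from_config(tmp_path: Path, config: em.SynthConfig):
    """Full pipeline over a generated corpus; returns (map, report, truth)."""
    e_path, i_path, truth = write_corpus(tmp_path, config)
    disease_map, report = em.build_map_from_csv(
        e_path, i_path, created=FIXED_CREATED
    )
    return disease_map, report, truth


def build_from_rows(
    entities: list[em.EntityRow],
    rows: list[em.InteractionRow],
    layout: bool = True,
) -> em.DiseaseMap:
    """Build a map directly from in-memory records (no CSV involved)."""
    lexicon = em.default_lexicon()
    evidences = [(row, em.categorize_evidence(row, lexicon)) for row in rows]
    disease_map = em.build_map(
        entities, evidences, lexicon_name=lexicon.name, created=FIXED_CREATED
    )
    if layout:
        disease_map = em.assign_layout(disease_map)
    return disease_map


def row(
    source: str,
    target: str,
    pmid: int,
    year: int = 2000,
    verbs: tuple[str, ...] = ("binds",),
) -> em.InteractionRow:
    return em.InteractionRow(
        source_id=source,
        target_id=target,
        pmid=pmid,
        year=year,
        sentence=f"{source} {' '.join(verbs) or 'co-occurs with'} {target}.",
        verbs=verbs,
    )


@pytest.fixture
def two_entities() -> list[em.EntityRow]:
    return [
        em.EntityRow("E1", "CFTR", "cytoplasm"),
        em.EntityRow("E2", "NHERF1", "plasma membrane"),
    ]
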