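"""Reading and validating the two-CSV text-mining exchange format.

Upstream text miners hand over two tables:

* an **entity table** (``entity_id,label,compartment``) listing every mined
  molecular entity with its subcellular localization, and
* an **interaction table** (``source_id,target_id,pmid,year,sentence,verbs``)
  with one row per sentence-level mention: the two entities, the PubMed ID
  and publication year of the source article, the evidence sentence, and
  the verbs found in it (joined with an intra-field separator).

Rows that violate the contract are reported in an :class:`IngestReport`
and skipped, so dirty input is surfaced rather than hidden; the ``strict``
flag turns any error into an exception instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

ENTITY_COLUMNS = ("entity_id", "label", "compartment")
INTERACTION_COLUMNS = ("source_id", "target_id", "pmid", "year", "sentence", "verbs")

YEAR_MIN, YEAR_MAX = 1800, 2100


@dataclass(frozen=True)
class CsvDialect:
    """CSV reading/writing configuration for the exchange format."""

    delimiter: str = ","
    quotechar: str = '"'
    encoding: str = "utf-8"
    verb_separator: str = ";"


DEFAULT_DIALECT = CsvDialect()


@dataclass(frozen=True)
class EntityRow:
    entity_id: str
    label: str
    compartment: str


@dataclass(frozen=True)
class InteractionRow:
    source_id: str
    target_id: str
    pmid: int
    year: int
    sentence: str
    verbs: tuple[str, ...]


@dataclass
class IngestReport:
    """Outcome of one ingest pass: counts plus per-row diagnostics.

    ``warnings`` and ``errors`` hold ``(line_number, message)`` pairs where
    the line number counts physical file lines (header = line 1).
    """

    n_entities: int = 0
    n_interaction_rows: int = 0
    warnings: list[tuple[int, str]] = field(default_factory=list)
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


class IngestError(ValueError):
    """Raised in strict mode, or for structurally unreadable input."""

    def __init__(self, message: str, report: IngestReport | None = None):
        super().__init__(message)
        self.report = report


def _open_table(path: Path, dialect: CsvDialect, expected: tuple[str, ...]):
    if not path.exists():
        raise IngestError(f"input file not found: {path}")
    fh = path.open(newline="", encoding=dialect.encoding)
    reader = csv.reader(fh, delimiter=dialect.delimiter, quotechar=dialect.quotechar)
    header = next(reader, None)
    if header is None:
        fh.close()
        raise IngestError(f"{path}: empty file, header row required")
    header = [h.strip() for h in header]
    missing = [c for c in expected if c not in header]
    if missing:
        fh.close()
        raise IngestError(f"{path}: missing required column(s): {', '.join(missing)}")
    index = {c: header.index(c) for c in expected}
    return fh, reader, index


def read_entities(
    path: str | Path,
    dialect: CsvDialect = DEFAULT_DIALECT,
    strict: bool = False,
) -> tuple[list[EntityRow], IngestReport]:
    """Read the entity table; duplicate ids and empty fields become errors."""
    path = Path(path)
    report = IngestReport()
    rows: list[EntityRow] = []
    seen: set[str] = set()
    fh, reader, idx = _open_table(path, dialect, ENTITY_COLUMNS)
    with fh:
        for lineno, rec in enumerate(reader, start=2):
            if not rec or all(not c.strip() for c in rec):
                continue
            if len(rec) < len(ENTITY_COLUMNS):
                report.errors.append((lineno, f"expected {len(ENTITY_COLUMNS)} fields, got {len(rec)}"))
                continue
            entity_id = rec[idx["entity_id"]].strip()
            label = rec[idx["label"]].strip()
            compartment = rec[idx["compartment"]].strip()
            if not entity_id or not label or not compartment:
                report.errors.append((lineno, "entity_id, label and compartment must be non-empty"))
                continue
            if entity_id in seen:
                report.errors.append((lineno, f"duplicate entity_id {entity_id!r}"))
                continue
            seen.add(entity_id)
            rows.append(EntityRow(entity_id, label, compartment))
    report.n_entities = len(rows)
    if strict and report.errors:
        raise IngestError(f"{path}: {len(report.errors)} bad row(s) in strict mode", report)
    return rows, report


def read_interactions(
    path: str | Path,
    entities: list[EntityRow],
    dialect: CsvDialect = DEFAULT_DIALECT,
    strict: bool = False,
) -> tuple[list[InteractionRow], IngestReport]:
    """Read the interaction table, resolving entity references.

    The ``verbs`` field is split on ``dialect.verb_separator``; an empty
    verbs field yields an empty tuple (such rows categorize as undefined
    downstream). Rows referencing unknown entities, or with non-numeric
    pmid/year, become errors and are skipped.
    """
    path = Path(path)
    known = {e.entity_id for e in entities}
    report = IngestReport()
    rows: list[InteractionRow] = []
    fh, reader, idx = _open_table(path, dialect, INTERACTION_COLUMNS)
    with fh:
        for lineno, rec in enumerate(reader, start=2):
            if not rec or all(not c.strip() for c in rec):
                continue
            if len(rec) < len(INTERACTION_COLUMNS):
                report.errors.append((lineno, f"expected {len(INTERACTION_COLUMNS)} fields, got {len(rec)}"))
                continue
            source_id = rec[idx["source_id"]].strip()
            target_id = rec[idx["target_id"]].strip()
            bad = [e for e in (source_id, target_id) if e not in known]
            if bad:
                report.errors.append((lineno, f"unknown entity {', '.join(bad)}"))
                continue
            try:
                pmid = int(rec[idx["pmid"]].strip())
                year = int(rec[idx["year"]].strip())
            except ValueError:
                report.errors.append((lineno, "pmid and year must be integers"))
                continue
            if pmid <= 0:
                report.errors.append((lineno, f"pmid must be positive, got {pmid}"))
                continue
            if not (YEAR_MIN <= year <= YEAR_MAX):
                report.errors.append((lineno, f"year {year} outside {YEAR_MIN}..{YEAR_MAX}"))
                continue
            sentence = rec[idx["sentence"]].strip()
            if not sentence:
                report.errors.append((lineno, "sentence must be non-empty"))
                continue
            verbs = tuple(
                v.strip()
                for v in rec[idx["verbs"]].split(dialect.verb_separator)
                if v.strip()
            )
            rows.append(InteractionRow(source_id, target_id, pmid, year, sentence, verbs))
    report.n_interaction_rows = len(rows)
    if strict and report.errors:
        raise IngestError(f"{path}: {len(report.errors)} bad row(s) in strict mode", report)
    return rows, report
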