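"""Verb-to-category mapping and evidence aggregation.

Text-mined interaction evidence arrives as a list of verbs per sentence.
Each verb is looked up in a :class:`VerbLexicon` mapping it to one of the
three lexical categories ``activate``, ``inhibit`` or ``neutral``; verbs
absent from the lexicon are ``undefined``.  Per-sentence categories are then
aggregated, and at the edge level conflicting directional evidence
(activation *and* inhibition reported by different publications) yields the
fifth, edge-only category ``incoherent``.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping


class InteractionCategory(str, Enum):
    """Interaction category of a verb, a sentence, or an aggregated edge.

    ``incoherent`` exists only at the edge level: it marks an interaction
    whose accumulated evidence supports both activation and inhibition.
    Verb- and evidence-level categories are restricted to the other four.
    """

    ACTIVATE = "activate"
    INHIBIT = "inhibit"
    NEUTRAL = "neutral"
    UNDEFINED = "undefined"
    INCOHERENT = "incoherent"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


#: Categories a single verb or a single evidence sentence may carry.
EVIDENCE_CATEGORIES = (
    InteractionCategory.ACTIVATE,
    InteractionCategory.INHIBIT,
    InteractionCategory.NEUTRAL,
    InteractionCategory.UNDEFINED,
)

_LEXICON_CATEGORIES = {
    InteractionCategory.ACTIVATE,
    InteractionCategory.INHIBIT,
    InteractionCategory.NEUTRAL,
}

# punctuation stripped from verb tokens before lookup
_PUNCT = " \t\r\n.,;:!?\"'()[]{}<>-_/\\"


class LexiconError(ValueError):
    """Raised for malformed lexicon files or entries."""


@dataclass(frozen=True)
class VerbLexicon:
    """Mapping from normalized (lowercase) verb form to its category.

    Keys must be lowercase and unique; values are restricted to
    ``activate``/``inhibit``/``neutral`` — absence from the lexicon *is*
    the ``undefined`` category, so no key may map to it explicitly.
    """

    entries: Mapping[str, InteractionCategory]
    name: str = "custom"

    def __post_init__(self) -> None:
        for verb, cat in self.entries.items():
            if verb != verb.lower().strip(_PUNCT) or not verb:
                raise LexiconError(f"lexicon key not normalized: {verb!r}")
            if cat not in _LEXICON_CATEGORIES:
                raise LexiconError(
                    f"lexicon entry {verb!r} maps to {cat.value!r}; only "
                    "activate/inhibit/neutral are allowed"
                )

    def __contains__(self, verb: str) -> bool:
        return verb in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EvidenceRecord:
    """One sentence-level mention of an interaction in one publication."""

    pmid: int
    year: int
    sentence: str
    verbs: tuple[str, ...]
    verb_categories: tuple[InteractionCategory, ...]
    evidence_category: InteractionCategory = field(default=InteractionCategory.UNDEFINED)

    def __post_init__(self) -> None:
        if len(self.verbs) != len(self.verb_categories):
            raise ValueError("verb_categories must align 1:1 with verbs")


def normalize_verb(verb: str) -> str:
    """Lowercase a verb token and strip surrounding punctuation."""
    return verb.strip(_PUNCT).lower()


def categorize_verb(verb: str, lexicon: VerbLexicon) -> InteractionCategory:
    """Look up a single verb; unknown verbs are ``undefined``.

    Total function: any string is accepted, normalization (lowercase +
    punctuation strip) happens before lookup.
    """
    return lexicon.entries.get(normalize_verb(verb), InteractionCategory.UNDEFINED)


def aggregate_categories(
    categories: Iterable[InteractionCategory],
) -> InteractionCategory:
    """Fold a list of verb- or evidence-level categories into one.

    Multiset semantics (order- and duplication-invariant):

    * ``activate`` and ``inhibit`` both present → ``incoherent``;
    * exactly one of the two directional categories present → that one;
    * otherwise ``neutral`` if present;
    * otherwise ``undefined`` (which also covers the empty list).
    """
    present = set(categories)
    act = InteractionCategory.ACTIVATE in present
    inh = InteractionCategory.INHIBIT in present
    if act and inh:
        return InteractionCategory.INCOHERENT
    if act:
        return InteractionCategory.ACTIVATE
    if inh:
        return InteractionCategory.INHIBIT
    if InteractionCategory.NEUTRAL in present:
        return InteractionCategory.NEUTRAL
    return InteractionCategory.UNDEFINED


def categorize_evidence(row, lexicon: VerbLexicon) -> EvidenceRecord:
    """Categorize one interaction row into an :class:`EvidenceRecord`.

    Each verb is categorized individually; the sentence-level category is
    the aggregate of the verb categories, except that a within-sentence
    activate/inhibit conflict demotes to ``undefined`` — ``incoherent`` is
    reserved for cross-evidence conflict at the edge level.

    ``row`` is any object with ``pmid``, ``year``, ``sentence`` and
    ``verbs`` attributes (normally an :class:`evimap.ingest.InteractionRow`).
    """
    verb_categories = tuple(categorize_verb(v, lexicon) for v in row.verbs)
    cat = aggregate_categories(verb_categories)
    if cat is InteractionCategory.INCOHERENT:
        cat = InteractionCategory.UNDEFINED
    return EvidenceRecord(
        pmid=row.pmid,
        year=row.year,
        sentence=row.sentence,
        verbs=tuple(row.verbs),
        verb_categories=verb_categories,
        evidence_category=cat,
    )


def load_lexicon(path: str | Path, name: str | None = None) -> VerbLexicon:
    """Load a two-column ``verb,category`` CSV lexicon.

    A header row ``verb,category`` is accepted and skipped; verbs are
    normalized on load so inflected forms may be listed in any case.
    """
    path = Path(path)
    entries: dict[str, InteractionCategory] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, rec in enumerate(csv.reader(fh), start=1):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) != 2:
                raise LexiconError(f"{path}:{lineno}: expected 2 columns, got {len(rec)}")
            verb, cat = rec[0].strip(), rec[1].strip().lower()
            if lineno == 1 and (verb, cat) == ("verb", "category"):
                continue
            try:
                category = InteractionCategory(cat)
            except ValueError:
                raise LexiconError(f"{path}:{lineno}: unknown category {cat!r}") from None
            key = normalize_verb(verb)
            if key in entries:
                raise LexiconError(f"{path}:{lineno}: duplicate verb {key!r}")
            entries[key] = category
    return VerbLexicon(entries=entries, name=name or path.name)


def default_lexicon() -> VerbLexicon:
    """The lexicon shipped with the package (~60 common interaction verbs)."""
    res = importlib.resources.files("evimap.data").joinpath("verb_lexicon.csv")
    with importlib.resources.as_file(res) as path:
        return load_lexicon(path, name="evimap-default")
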