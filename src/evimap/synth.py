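"""Seeded generator of synthetic text-mining corpora with ground truth.

Every other module is exercised against corpora built here: the generator
plants a known class and a known distinct-publication count on every edge,
emits the two-CSV exchange format for them, and returns the ground truth so
tests can demand exact recovery through ingest → categorize → build_map.

Sentences are template text ("X strongly activates Y in the cytoplasm.");
the categorizer consumes the verbs column, not the sentence, so realistic
prose would add nothing.  What the generator deliberately does *not*
emulate: NER errors, entity-name synonymy, negated or speculative
sentences — those are upstream text-miner concerns.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .categorize import InteractionCategory, VerbLexicon, default_lexicon
from .ingest import EntityRow, InteractionRow
from .exporter import write_entities_csv, write_interactions_csv

#: verbs guaranteed absent from any sane lexicon → planted undefined edges
_NONSENSE_VERBS = ("flurbs", "zorps", "quibbles", "snarfles", "blintzes")

_COMPARTMENT_POOL = (
    "extracellular",
    "plasma membrane",
    "cytoplasm",
    "endoplasmic reticulum",
    "golgi apparatus",
    "mitochondrion",
    "endosome",
    "nucleus",
)


@dataclass(frozen=True)
class SynthConfig:
    """Shape of a synthetic corpus.

    ``conflict_rate`` / ``undefined_rate`` are the fractions of edges
    planted as incoherent (mixed activating + inhibiting publications) and
    undefined (no lexicon verbs); the remaining edges split evenly across
    activate / inhibit / neutral.  Planted counts use round-half-away-from-
    zero so they are exact, not expectations.
    """

    n_compartments: int = 5
    n_entities: int = 30
    n_edges: int = 60
    pmids_per_edge: tuple[int, int] = (1, 5)
    conflict_rate: float = 0.1
    undefined_rate: float = 0.1
    year_range: tuple[int, int] = (1990, 2020)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compartments < 1 or self.n_entities < 1 or self.n_edges < 0:
            raise ValueError("n_compartments, n_entities >= 1 and n_edges >= 0 required")
        if not (0 <= self.conflict_rate + self.undefined_rate <= 1):
            raise ValueError("conflict_rate + undefined_rate must lie in [0, 1]")
        if self.n_edges > self.n_entities * (self.n_entities - 1):
            raise ValueError("n_edges exceeds the number of distinct directed pairs")
        lo, hi = self.pmids_per_edge
        if not (1 <= lo <= hi):
            raise ValueError("pmids_per_edge must be (lo, hi) with 1 <= lo <= hi")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range start must not exceed end")


@dataclass(frozen=True)
class PlantedEdge:
    source_id: str
    target_id: str
    edge_class: InteractionCategory
    weight: int  # distinct pmids
    years: tuple[int, ...]  # one per evidence row


@dataclass
class GroundTruth:
    """What was planted, keyed by directed entity pair."""

    edges: dict[tuple[str, str], PlantedEdge] = field(default_factory=dict)
    n_evidence_rows: int = 0


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _verbs_of(lexicon: VerbLexicon, category: InteractionCategory) -> list[str]:
    return sorted(v for v, c in lexicon.entries.items() if c is category)


def _sentence(src: str, tgt: str, verb: str, compartment: str) -> str:
    return f"{src} strongly {verb} {tgt} in the {compartment}."


def generate_corpus(
    config: SynthConfig, lexicon: VerbLexicon | None = None
) -> tuple[str, str, GroundTruth]:
    """Emit (entities CSV, interactions CSV, ground truth), deterministically.

    Each planted edge receives one evidence row per distinct PubMed ID,
    with verbs drawn from the lexicon to match the planted class; an
    incoherent edge gets at least one activating and one inhibiting
    publication, an undefined edge only out-of-lexicon verbs.  Extra rows
    reusing an already-planted PubMed ID are occasionally added so that
    distinct-publication counting (not row counting) is what recovery
    tests actually exercise.  PubMed IDs never collide across edges.
    """
    lexicon = lexicon or default_lexicon()
    rng = random.Random(config.seed)

    n_comp = min(config.n_compartments, len(_COMPARTMENT_POOL))
    compartments = list(_COMPARTMENT_POOL[:n_comp])
    entities = [
        EntityRow(
            entity_id=f"E{i:03d}",
            label=f"GENE{i:03d}",
            compartment=rng.choice(compartments),
        )
        for i in range(1, config.n_entities + 1)
    ]
    comp_of = {e.entity_id: e.compartment for e in entities}
    label_of = {e.entity_id: e.label for e in entities}

    # distinct directed pairs, sampled without replacement
    ids = [e.entity_id for e in entities]
    pairs: list[tuple[str, str]] = []
    taken: set[tuple[str, str]] = set()
    while len(pairs) < config.n_edges:
        pair = (rng.choice(ids), rng.choice(ids))
        if pair[0] != pair[1] and pair not in taken:
            taken.add(pair)
            pairs.append(pair)

    n_conflict = _round_half_away(config.conflict_rate * config.n_edges)
    n_undefined = _round_half_away(config.undefined_rate * config.n_edges)
    n_undefined = min(n_undefined, config.n_edges - n_conflict)
    classes = [InteractionCategory.INCOHERENT] * n_conflict
    classes += [InteractionCategory.UNDEFINED] * n_undefined
    plain = (
        InteractionCategory.ACTIVATE,
        InteractionCategory.INHIBIT,
        InteractionCategory.NEUTRAL,
    )
    classes += [plain[i % 3] for i in range(config.n_edges - len(classes))]
    rng.shuffle(classes)

    act_verbs = _verbs_of(lexicon, InteractionCategory.ACTIVATE)
    inh_verbs = _verbs_of(lexicon, InteractionCategory.INHIBIT)
    neu_verbs = _verbs_of(lexicon, InteractionCategory.NEUTRAL)

    next_pmid = 1_000_000
    rows: list[InteractionRow] = []
    truth = GroundTruth()
    lo, hi = config.pmids_per_edge
    for (src, tgt), planted_class in zip(pairs, classes):
        k = rng.randint(lo, hi)
        if planted_class is InteractionCategory.INCOHERENT:
            k = max(k, 2)
        pmids = list(range(next_pmid, next_pmid + k))
        next_pmid += k
        years = tuple(
            rng.randint(config.year_range[0], config.year_range[1]) for _ in pmids
        )

        if planted_class is InteractionCategory.INCOHERENT:
            # split publications between the two directions, >=1 each
            n_act = rng.randint(1, k - 1)
            verb_pools = [act_verbs] * n_act + [inh_verbs] * (k - n_act)
        elif planted_class is InteractionCategory.ACTIVATE:
            verb_pools = [act_verbs] * k
        elif planted_class is InteractionCategory.INHIBIT:
            verb_pools = [inh_verbs] * k
        elif planted_class is InteractionCategory.NEUTRAL:
            verb_pools = [neu_verbs] * k
        else:
            verb_pools = [list(_NONSENSE_VERBS)] * k

        all_years = list(years)
        for pmid, year, pool in zip(pmids, years, verb_pools):
            verbs = [rng.choice(pool)]
            # a neutral co-mention verb alongside a directional one is common
            # in real sentences and must not change the class
            if planted_class in (
                InteractionCategory.ACTIVATE,
                InteractionCategory.INHIBIT,
                InteractionCategory.INCOHERENT,
            ) and rng.random() < 0.3:
                verbs.append(rng.choice(neu_verbs))
            rows.append(
                InteractionRow(
                    source_id=src,
                    target_id=tgt,
                    pmid=pmid,
                    year=year,
                    sentence=_sentence(label_of[src], label_of[tgt], verbs[0], comp_of[src]),
                    verbs=tuple(verbs),
                )
            )
        # duplicate mention within an already-counted publication
        if k >= 2 and rng.random() < 0.5:
            i = rng.randrange(k)
            dup_pool = verb_pools[i]
            verb = rng.choice(dup_pool)
            rows.append(
                InteractionRow(
                    source_id=src,
                    target_id=tgt,
                    pmid=pmids[i],
                    year=years[i],
                    sentence=_sentence(label_of[src], label_of[tgt], verb, comp_of[src]),
                    verbs=(verb,),
                )
            )
            all_years.append(years[i])

        truth.edges[(src, tgt)] = PlantedEdge(
            source_id=src,
            target_id=tgt,
            edge_class=planted_class,
            weight=k,
            years=tuple(all_years),
        )

    truth.n_evidence_rows = len(rows)
    return write_entities_csv(entities), write_interactions_csv(rows), truth
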