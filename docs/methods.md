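# Methods

## Scope and data model

evimap operates downstream of an independent, exchangeable text-mining
system. Named-entity recognition, identifier normalization and relation
extraction are that system's job; evimap's contract starts at two CSV
tables — entities (`entity_id,label,compartment`) and sentence-level
interaction evidence (`source_id,target_id,pmid,year,sentence,verbs`) —
and ends at an expert-validated interaction list. The column names are
fixed by this package (the exchange format is reproducible only if the
header is part of the contract); delimiter, quoting and the intra-field
verb separator (default `;`) are configurable. One CSV row is one
sentence-level mention; aggregation into edges happens inside evimap, so
upstream systems need no grouping logic. Entity matching is exact and
case-sensitive: resolving synonymy is an NER concern, and silently
merging ids here would mask upstream errors. Multi-localized entities are
not modelled — a node has exactly one parent compartment, and an upstream
miner that resolves an entity to two compartments must emit two entities.

Malformed rows (unknown entity, non-numeric pmid/year, out-of-range year,
empty sentence, duplicate entity id) are collected per row number in an
ingest report and skipped; the `strict` flag makes them fatal. A curation
tool must surface dirty input, not hide it, so skipping is the default and
the report is part of the API.

## Verb categorization

A verb lexicon maps normalized verb forms to `activate`, `inhibit` or
`neutral`. Normalization is lowercase plus surrounding-punctuation strip —
deliberately *not* stemming or lemmatization: a deterministic,
dependency-free lookup is predictable for curators, and the lexicon simply
lists inflected forms. Verbs absent from the lexicon are `undefined`; the
lexicon may not map a verb to `undefined` explicitly (absence *is* that
category). The packaged default (~68 forms over the stems
activate/stimulate/induce/enhance/upregulate…, inhibit/suppress/block/
repress/downregulate…, bind/interact/phosphorylate/associate/complex…) is
a documented, replaceable artifact (`--lexicon` on the CLI); any serious
deployment will curate its own.

## Aggregation and the incoherent class

Category aggregation uses multiset semantics (order- and
duplication-invariant):

* `activate` and `inhibit` both present → `incoherent`;
* exactly one directional category present → that category;
* otherwise `neutral` if present, else `undefined`.

`incoherent` is an *edge-only* class: it marks an interaction whose
accumulated publications disagree about direction, which is precisely the
case an expert must adjudicate. Within a single sentence, a
directional conflict demotes to `undefined` instead — one sentence
containing both "activates" and "inhibits" is more likely a parsing
artifact than genuine cross-study disagreement, and reserving
`incoherent` for cross-evidence conflict keeps its meaning sharp. This
trigger rule is a design decision of this package: the rendered class
exists in the field's viewers, but its defining condition is not
standardized.

Edge weight is the number of distinct PubMed IDs among an edge's
evidence, not the row count: three sentences from one paper are one
publication's worth of support.

## Layout

The layout is a deterministic banded grid, not a force simulation.
Compartments are stacked top-to-bottom in canonical cellular order
(extracellular, plasma membrane, membrane, cytoplasm, ER, Golgi,
mitochondrion, endosome, lysosome, nucleus; unknown names sort
alphabetically below), overridable via `LayoutConfig.compartment_order`.
Within a band, nodes are sorted by (label, id) and placed row-major on a
near-square grid with pitch `spacing` (default 80 layout units ≈ screen
pixels) inset by `margin` (default 40) from the band border; bands share
the widest band's width and are separated by `band_gap` (10). Any
positive margin guarantees strict containment, and the geometry bounds
pairwise node distance below by `spacing` within a band and by
`2·margin + band_gap` across bands. Bands grow to fit their nodes; there
is no overflow error. Coordinates are x-rightward, y-downward from a
top-left origin (the screen convention of browser graph renderers).
Determinism over aesthetics: identical inputs must serialize
byte-identically so maps can be diffed and regression-tested; users of a
viewer can still drag nodes afterwards.

## Serialization

The map JSON is an object `{"meta": ..., "elements": [...]}` where
`elements` is a flat list in the compound-node convention: compartments
first (container nodes carrying a `bbox` in their data — the presence of
`bbox` is the compartment discriminator on import), then entity nodes
with `parent`, then edges with `classes` and a `references` list holding
every evidence sentence with its PubMed ID, year, verbs and per-verb
categories. `meta` carries provenance (creation time, input file names,
lexicon identity, tool version) and the review audit trail; creation
timestamps are injectable so exports can be pinned in tests. Coordinates
are written at fixed 2-decimal precision and key order is fixed, making
`serialize ∘ parse ∘ serialize` byte-identical. The format is described
by the shipped JSON schema (`schema/map-elements.schema.json`), which is
public API; documents are validated on both export and import by a small
validator implementing the schema-language subset the schema uses, and
import errors name the offending element and key. Keys outside the schema
are rejected on import rather than preserved opaquely — the schema is the
contract.

SBGN-ML output uses the 0.2 activity-flow language: compartment glyphs
with the layout's bounding boxes, `biological activity` glyphs (60×30
units, centred on the node position — the 40-unit layout margin keeps
them inside their compartment), and arcs: `stimulation` for activate,
`inhibition` for inhibit, and the generic `influence` for neutral,
undefined and incoherent, since activity flow has no arc for those; the
original class and weight travel in an extension annotation, so no
information is lost. SBML export is out of scope.

The review CSV has one row per edge, sorted by edge id, with source and
target labels, class, weight, the current status (spelled `unreviewed`,
`accepted`, `declined`, `further_inspection_needed`) and the ascending,
separator-joined PubMed IDs.

## Curation semantics

Filtering keeps exactly the edges whose class is allowed (an empty
allow-set means all) and whose weight meets the minimum publication
count; it never touches nodes or compartments — hiding isolated nodes is
a viewer concern, and keeping the filter a pure edge operation makes it
idempotent and makes class- and weight-filtering commute.

Timeline snapshots are **cumulative**: the snapshot at year *y* keeps
evidence with publication year ≤ *y*, drops edges left without evidence,
and recomputes weight and class from what remains. Accumulating
literature read as knowledge-to-date is the natural interpretation, and
it yields the monotone-containment property (edge sets nest along the
series) that the tests assert. Per-window snapshots are deliberately not
offered: two semantics behind one switch invite silent misreads.

Review decisions are last-write-wins on the edge's current status, with
every decision (status, optional note, timestamp) appended to an audit
trail in the map metadata — a single current status matches how a viewer
displays it, while the trail supports collaborative sessions. Decisions
never alter topology, weights or classes. The review queue
(`next_unreviewed`) iterates unreviewed edges in sorted-id order,
cyclically, so two curators see the same sequence. No multi-user locking
or undo beyond the audit trail is attempted.

## Synthetic corpora and what passing tests mean

The `synth` module generates seeded corpora with *planted* ground truth:
each edge gets a target class and a target distinct-publication count,
evidence sentences are templated around lexicon verbs matching that class
(incoherent edges receive at least one activating and one inhibiting
publication; undefined edges only out-of-lexicon verbs), PubMed IDs never
collide across edges, duplicate mentions within an already-counted
publication are injected so distinct-ID counting is actually exercised,
and about 30 % of directional sentences also carry a neutral co-mention
verb, which must not change the class. Planted fractions use
round-half-away-from-zero so example counts are exact. Default study
conditions: 5 compartments, 30 entities, 60 edges, 1–5 publications per
edge, 10 % incoherent, 10 % undefined, years uniform on 1990–2020 —
sized like a focused single-pathway curation effort and spanning the
timeline the snapshot feature targets.

What the generator does *not* emulate — NER errors, synonym collisions,
negation, speculation, mis-parsed sentences — bounds what green tests
mean: they certify the deterministic pipeline (categorization,
aggregation, counting, layout, serialization, curation operations) is
exact, not that any text miner's output is correct. That division of
labour is the point of the tool: machine recall, expert precision.

## Verification sizes and numerical choices

The acceptance checks run 50 corpora (10–50 entities, up to 200 edges)
for ground-truth recovery, all 5 460 category lists up to length 6
against an independently written rule table, 100 fixtures for JSON round
trips, 100 random map/filter pairs against a brute-force oracle, and 10
maps each for timeline, layout, format and review checks — sizes chosen
to cover the combinatorics several times over while keeping the whole
suite in seconds. All randomness is seeded; hypothesis runs
derandomized. Ties in layout placement are broken by (label, id); years
at exactly the cutoff are included in the snapshot (≤, not <); an empty
map serializes to an empty element list and is valid.
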