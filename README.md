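# evimap

**evimap** turns raw text-mining output into an expert-reviewable *disease
map* — a systems-biology overview of the molecular interactions underlying a
disease.

Modern text miners can read thousands of abstracts and emit candidate
interactions ("protein A activates protein B, PMID 12345"), but they cannot
replace the domain expert who decides which of those candidates are real.
evimap sits between the two: it ingests the miner's output, aggregates the
sentence-level evidence into categorized, evidence-weighted interaction
edges laid out in a cell-like compartmental view, and supports the curation
loop — filtering, publication-year timelines, per-edge accept / decline /
needs-inspection decisions — before exporting validated interactions for
use in a disease map. It is written for computational biologists and
biocurators who run a text-mining pipeline and need to review its results.

## The model

The input is two CSV tables: entities with their subcellular localization,
and one row per *sentence-level mention* of an interaction —
`(source, target, pmid, year, sentence, verbs)`.

* **Verb categorization.** Each verb is looked up in a replaceable lexicon
  mapping verb forms to `activate`, `inhibit` or `neutral`; unknown verbs
  are `undefined`. A sentence's category is the aggregate of its verbs.
* **Evidence aggregation.** All mentions of a directed pair (s → t) merge
  into one edge. The edge **weight** is the number of *distinct* PubMed IDs
  supporting it (the quantity viewers render as edge thickness). The edge
  **class** aggregates the per-sentence categories with the precedence
  `undefined < neutral < {activate | inhibit}`; evidence for *both*
  activation and inhibition yields the fifth, edge-only class
  `incoherent` — the interactions most worth an expert's attention.
* **Layout.** Compartments become vertically stacked bands in canonical
  cellular order (extracellular → membrane → cytoplasm → organelles →
  nucleus); nodes sit on a per-band grid. The layout is deterministic, so
  exports are byte-reproducible and diffable.
* **Timeline.** A snapshot at year *y* keeps only evidence published in or
  before *y* and recomputes weights and classes, reconstructing the state
  of knowledge at that time (by default 1990–2020 in 5-year steps).

Exports: a lossless Cytoscape-style elements JSON (schema shipped at
`src/evimap/schema/map-elements.schema.json`), SBGN-ML 0.2 activity-flow,
and a review CSV with one row per edge and its current status.

## Worked example

```bash
python examples/01_build_map.py
```

```
ingested 30 entities and 191 sentence-level evidence rows (0 bad rows)
map: 5 compartments, 30 nodes, 60 edges
    activate: 16 edges
  incoherent: 6 edges
     inhibit: 16 edges
     neutral: 16 edges
   undefined: 6 edges
best-supported edge: E002->E008 (5 distinct publications, class incoherent)
```

The 191 sentence rows collapse to 60 directed edges; six edges carry
conflicting directional evidence (`incoherent`) and six have no lexicon
verb at all (`undefined`). The best-supported edge is backed by five
distinct publications — and is itself incoherent, i.e. exactly the kind of
interaction the review workflow exists for. The other examples cover
filtering and the timeline (`02`), the review loop and CSV export (`03`),
and the JSON / SBGN-ML round trip (`04`).

The same pipeline is available from the shell:

```bash
evimap synth --out-dir corpus --seed 7
evimap build -e corpus/entities.csv -i corpus/interactions.csv -o map.json --sbgn map.sbgn
evimap review map.json --set "E001->E002=accepted" --csv review.csv
evimap snapshot map.json --start 1990 --end 2020 --step 5 --out-dir snaps/
```

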