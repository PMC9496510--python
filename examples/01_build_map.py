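"""Build a disease map from the two-CSV text-mining exchange format.

Generates a small synthetic corpus (30 entities, 60 interactions with known
classes), runs ingest -> verb categorization -> evidence aggregation ->
cellular layout, and prints what the map contains.
"""

import tempfile
from collections import Counter
from pathlib import Path

import evimap as em

workdir = Path(tempfile.mkdtemp())
entities_csv, interactions_csv, truth = em.generate_corpus(em.SynthConfig(seed=7))
(workdir / "entities.csv").write_text(entities_csv)
(workdir / "interactions.csv").write_text(interactions_csv)

disease_map, report = em.build_map_from_csv(
    workdir / "entities.csv", workdir / "interactions.csv"
)

print(f"ingested {report.n_entities} entities and "
      f"{report.n_interaction_rows} sentence-level evidence rows "
      f"({len(report.errors)} bad rows)")
print(f"map: {len(disease_map.compartments)} compartments, "
      f"{len(disease_map.nodes)} nodes, {len(disease_map.edges)} edges")

# Edge classes summarize what the literature says about each interaction;
# 'incoherent' marks edges with both activating and inhibiting publications.
classes = Counter(e.edge_class.value for e in disease_map.edges)
for name, count in sorted(classes.items()):
    print(f"  {name:>10}: {count} edges")

heaviest = max(disease_map.edges, key=lambda e: e.weight)
print(f"best-supported edge: {heaviest.edge_id} "
      f"({heaviest.weight} distinct publications, class {heaviest.edge_class.value})")
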