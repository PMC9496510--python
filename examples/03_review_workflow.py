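"""Expert review: iterate unreviewed edges, decide, export the review CSV.

Each decision sets the edge's current status (last write wins) and joins
the audit trail in the map's metadata, so a curation session is fully
reconstructable.
"""

import tempfile
from pathlib import Path

import evimap as em

workdir = Path(tempfile.mkdtemp())
entities_csv, interactions_csv, _ = em.generate_corpus(
    em.SynthConfig(n_entities=10, n_edges=8, seed=3)
)
(workdir / "e.csv").write_text(entities_csv)
(workdir / "i.csv").write_text(interactions_csv)
disease_map, _ = em.build_map_from_csv(workdir / "e.csv", workdir / "i.csv")

# walk the review queue the way the "next edge" button would
eid = em.next_unreviewed(disease_map)
edge = disease_map.edge_by_id(eid)
print(f"reviewing {eid} (class {edge.edge_class.value}, "
      f"{edge.weight} publications):")
for ev in edge.evidences[:2]:
    print(f"  PMID {ev.pmid} ({ev.year}): {ev.sentence}")

disease_map = em.apply_review(
    disease_map, em.ReviewDecision(eid, em.ReviewStatus.ACCEPTED, note="clear evidence")
)
second = em.next_unreviewed(disease_map, after=eid)
disease_map = em.apply_review(
    disease_map, em.ReviewDecision(second, em.ReviewStatus.DECLINED)
)

summary = em.review_summary(disease_map)
print("review progress:", ", ".join(f"{k}={v}" for k, v in summary.items()))
print(f"audit trail holds {len(disease_map.meta['review_audit'])} decisions")
print()
print(em.to_review_csv(disease_map))
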