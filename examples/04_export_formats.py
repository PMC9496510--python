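"""Export a laid-out map as viewer JSON and SBGN-ML, and reload it.

The elements JSON is lossless (a later session reloads the exact map,
review state included); the SBGN-ML document renders the same map in the
activity-flow notation of systems-biology tools.
"""

import tempfile
from pathlib import Path

import evimap as em

workdir = Path(tempfile.mkdtemp())
entities_csv, interactions_csv, _ = em.generate_corpus(
    em.SynthConfig(n_entities=8, n_edges=6, seed=5)
)
(workdir / "e.csv").write_text(entities_csv)
(workdir / "i.csv").write_text(interactions_csv)
disease_map, _ = em.build_map_from_csv(workdir / "e.csv", workdir / "i.csv")

json_text = em.to_map_json(disease_map)
(workdir / "map.json").write_text(json_text)
reloaded = em.from_map_json(json_text)
print(f"wrote map.json ({len(json_text)} bytes); "
      f"reload equals original: {reloaded == disease_map}")

sbgn_text = em.to_sbgnml(disease_map)
(workdir / "map.sbgn").write_text(sbgn_text)
n_glyphs = sbgn_text.count("<glyph")
n_arcs = sbgn_text.count("<arc")
print(f"wrote map.sbgn: {n_glyphs} glyphs "
      f"({len(disease_map.compartments)} compartments + {len(disease_map.nodes)} "
      f"activities), {n_arcs} arcs")
print(f"files in {workdir}")
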