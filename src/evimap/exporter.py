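"""Serialization of disease maps: graph JSON, SBGN-ML, review CSV.

The primary interchange format is an elements-JSON document in the style of
browser graph renderers: a flat list where compartments appear first as
container nodes carrying their bounding box, then entity nodes with a
``parent`` reference, then edges with ``classes`` and the full per-sentence
``references`` evidence.  Serialization is lossless and byte-deterministic
(fixed key order, coordinates at 2-decimal precision), so
``parse(serialize(m)) == m`` and ``serialize(parse(doc)) == doc``.

SBGN-ML output uses the activity-flow sublanguage: compartment glyphs,
biological-activity glyphs, and stimulation / inhibition / influence arcs.

On import, keys outside the documented schema are rejected rather than
preserved: the schema is the contract of the format.
"""

from __future__ import annotations

import csv
import importlib.resources
import io
import json
import xml.etree.ElementTree as ET
from pathlib import Path

from . import schema_validator
from .categorize import EvidenceRecord, InteractionCategory
from .ingest import (
    ENTITY_COLUMNS,
    INTERACTION_COLUMNS,
    CsvDialect,
    DEFAULT_DIALECT,
    EntityRow,
    InteractionRow,
)
from .mapmodel import (
    Compartment,
    DiseaseMap,
    InteractionEdge,
    MapNode,
    Rect,
    ReviewStatus,
)

SBGN_NS = "http://sbgn.org/libsbgn/0.2"
EXTENSION_NS = "https://evimap.dev/sbgn-extension"

ACTIVITY_W, ACTIVITY_H = 60.0, 30.0


class ExportError(ValueError):
    """Raised for unserializable maps or invalid documents."""


def load_schema() -> dict:
    """The packaged map-elements JSON schema (part of the public API)."""
    res = importlib.resources.files("evimap.schema").joinpath(
        "map-elements.schema.json"
    )
    return json.loads(res.read_text(encoding="utf-8"))


def _r(value: float) -> float:
    return round(float(value), 2)


def _evidence_to_ref(ev: EvidenceRecord) -> dict:
    return {
        "pmid": ev.pmid,
        "year": ev.year,
        "sentence": ev.sentence,
        "verbs": list(ev.verbs),
        "verb_categories": [c.value for c in ev.verb_categories],
        "category": ev.evidence_category.value,
    }


def map_to_elements(disease_map: DiseaseMap) -> dict:
    """The JSON-able document: meta plus the flat element list."""
    if disease_map.nodes and not disease_map.has_layout:
        raise ExportError(
            "map has no layout (all node positions at the origin); "
            "run mapmodel.assign_layout before exporting"
        )
    elements: list[dict] = []
    for comp in disease_map.compartments:
        b = comp.bounds
        elements.append(
            {
                "group": "nodes",
                "data": {
                    "id": comp.compartment_id,
                    "label": comp.label,
                    "bbox": {
                        "x": _r(b.x),
                        "y": _r(b.y),
                        "width": _r(b.width),
                        "height": _r(b.height),
                    },
                },
                "position": {
                    "x": _r(b.x + b.width / 2),
                    "y": _r(b.y + b.height / 2),
                },
            }
        )
    for node in disease_map.nodes:
        elements.append(
            {
                "group": "nodes",
                "data": {"id": node.node_id, "label": node.label, "parent": node.parent},
                "position": {"x": _r(node.position[0]), "y": _r(node.position[1])},
            }
        )
    for edge in disease_map.edges:
        elements.append(
            {
                "group": "edges",
                "data": {
                    "id": edge.edge_id,
                    "source": edge.source,
                    "target": edge.target,
                    "weight": edge.weight,
                    "review_status": edge.review_status.value,
                    "references": [_evidence_to_ref(ev) for ev in edge.evidences],
                },
                "classes": edge.edge_class.value,
            }
        )
    return {"meta": disease_map.meta, "elements": elements}


def to_map_json(disease_map: DiseaseMap) -> str:
    """Serialize to the map-elements JSON document (validating first)."""
    document = map_to_elements(disease_map)
    problems = schema_validator.validate(document, load_schema())
    if problems:  # pragma: no cover - guards internal consistency
        raise ExportError("produced document violates schema: " + "; ".join(problems))
    return json.dumps(document, indent=2, ensure_ascii=False) + "\n"


def validate_document(document: dict) -> list[str]:
    """Schema + referential checks; messages name the offending element."""
    problems = schema_validator.validate(document, load_schema())
    if problems:
        return problems
    node_ids: set[str] = set()
    comp_ids: set[str] = set()
    for el in document["elements"]:
        if el["group"] == "nodes":
            (comp_ids if "bbox" in el["data"] else node_ids).add(el["data"]["id"])
    for el in document["elements"]:
        data = el["data"]
        if el["group"] == "nodes" and "parent" in data:
            if data["parent"] not in comp_ids:
                problems.append(
                    f"node {data['id']!r}: parent {data['parent']!r} is not a compartment"
                )
        elif el["group"] == "edges":
            for end in ("source", "target"):
                if data[end] not in node_ids:
                    problems.append(
                        f"edge {data['id']!r}: {end} {data[end]!r} is not a node"
                    )
            distinct = len({ref["pmid"] for ref in data["references"]})
            if data["weight"] != distinct:
                problems.append(
                    f"edge {data['id']!r}: weight {data['weight']} != "
                    f"{distinct} distinct pmids"
                )
    return problems


def _ref_to_evidence(ref: dict) -> EvidenceRecord:
    return EvidenceRecord(
        pmid=ref["pmid"],
        year=ref["year"],
        sentence=ref["sentence"],
        verbs=tuple(ref["verbs"]),
        verb_categories=tuple(InteractionCategory(c) for c in ref["verb_categories"]),
        evidence_category=InteractionCategory(ref["category"]),
    )


def from_map_json(document: str | dict) -> DiseaseMap:
    """Parse a map-elements document back into a :class:`DiseaseMap`.

    The document must validate against the packaged schema; violations are
    reported with the offending element id and key.
    """
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ExportError(f"not valid JSON: {exc}") from exc
    problems = validate_document(document)
    if problems:
        raise ExportError("invalid map document: " + "; ".join(problems))
    compartments: list[Compartment] = []
    nodes: list[MapNode] = []
    edges: list[InteractionEdge] = []
    for el in document["elements"]:
        data = el["data"]
        if el["group"] == "nodes" and "bbox" in data:
            b = data["bbox"]
            compartments.append(
                Compartment(
                    compartment_id=data["id"],
                    label=data["label"],
                    bounds=Rect(b["x"], b["y"], b["width"], b["height"]),
                )
            )
        elif el["group"] == "nodes":
            pos = el["position"]
            nodes.append(
                MapNode(
                    node_id=data["id"],
                    label=data["label"],
                    parent=data["parent"],
                    position=(pos["x"], pos["y"]),
                )
            )
        else:
            edges.append(
                InteractionEdge(
                    edge_id=data["id"],
                    source=data["source"],
                    target=data["target"],
                    edge_class=InteractionCategory(el["classes"]),
                    evidences=tuple(_ref_to_evidence(r) for r in data["references"]),
                    weight=data["weight"],
                    review_status=ReviewStatus(data["review_status"]),
                )
            )
    return DiseaseMap(
        compartments=compartments, nodes=nodes, edges=edges, meta=document["meta"]
    )


# ---------------------------------------------------------------------------
# review CSV and the two-CSV exchange format


def to_review_csv(disease_map: DiseaseMap, dialect: CsvDialect = DEFAULT_DIALECT) -> str:
    """One row per edge, sorted by edge id, with its current review status."""
    labels = {n.node_id: n.label for n in disease_map.nodes}
    out = io.StringIO()
    writer = csv.writer(
        out, delimiter=dialect.delimiter, quotechar=dialect.quotechar, lineterminator="\n"
    )
    writer.writerow(
        ["edge_id", "source_label", "target_label", "edge_class", "weight",
         "review_status", "pmids"]
    )
    for edge in sorted(disease_map.edges, key=lambda e: e.edge_id):
        pmids = dialect.verb_separator.join(str(p) for p in sorted(edge.pmids))
        writer.writerow(
            [
                edge.edge_id,
                labels.get(edge.source, edge.source),
                labels.get(edge.target, edge.target),
                edge.edge_class.value,
                edge.weight,
                edge.review_status.value,
                pmids,
            ]
        )
    return out.getvalue()


def write_entities_csv(
    entities: list[EntityRow], dialect: CsvDialect = DEFAULT_DIALECT
) -> str:
    out = io.StringIO()
    writer = csv.writer(
        out, delimiter=dialect.delimiter, quotechar=dialect.quotechar, lineterminator="\n"
    )
    writer.writerow(ENTITY_COLUMNS)
    for e in entities:
        writer.writerow([e.entity_id, e.label, e.compartment])
    return out.getvalue()


def write_interactions_csv(
    rows: list[InteractionRow], dialect: CsvDialect = DEFAULT_DIALECT
) -> str:
    out = io.StringIO()
    writer = csv.writer(
        out, delimiter=dialect.delimiter, quotechar=dialect.quotechar, lineterminator="\n"
    )
    writer.writerow(INTERACTION_COLUMNS)
    for r in rows:
        writer.writerow(
            [
                r.source_id,
                r.target_id,
                r.pmid,
                r.year,
                r.sentence,
                dialect.verb_separator.join(r.verbs),
            ]
        )
    return out.getvalue()


# ---------------------------------------------------------------------------
# SBGN-ML (activity flow)

#: edge class → SBGN AF arc class.  SBGN AF has no "incoherent" arc, so the
#: non-directional classes all map to the generic influence arc; the original
#: class travels in an extension annotation, losing nothing.
ARC_CLASS = {
    InteractionCategory.ACTIVATE: "stimulation",
    InteractionCategory.INHIBIT: "inhibition",
    InteractionCategory.NEUTRAL: "influence",
    InteractionCategory.UNDEFINED: "influence",
    InteractionCategory.INCOHERENT: "influence",
}


def to_sbgnml(disease_map: DiseaseMap) -> str:
    """Serialize to an SBGN-ML 0.2 activity-flow document."""
    if disease_map.nodes and not disease_map.has_layout:
        raise ExportError(
            "map has no layout; run mapmodel.assign_layout before SBGN export"
        )
    ET.register_namespace("", SBGN_NS)
    root = ET.Element(f"{{{SBGN_NS}}}sbgn")
    sbgn_map = ET.SubElement(root, f"{{{SBGN_NS}}}map", {"language": "activity flow"})
    for comp in disease_map.compartments:
        glyph = ET.SubElement(
            sbgn_map,
            f"{{{SBGN_NS}}}glyph",
            {"class": "compartment", "id": comp.compartment_id},
        )
        ET.SubElement(glyph, f"{{{SBGN_NS}}}label", {"text": comp.label})
        b = comp.bounds
        ET.SubElement(
            glyph,
            f"{{{SBGN_NS}}}bbox",
            {"x": str(_r(b.x)), "y": str(_r(b.y)),
             "w": str(_r(b.width)), "h": str(_r(b.height))},
        )
    for node in disease_map.nodes:
        glyph = ET.SubElement(
            sbgn_map,
            f"{{{SBGN_NS}}}glyph",
            {
                "class": "biological activity",
                "id": node.node_id,
                "compartmentRef": node.parent,
            },
        )
        ET.SubElement(glyph, f"{{{SBGN_NS}}}label", {"text": node.label})
        x, y = node.position
        ET.SubElement(
            glyph,
            f"{{{SBGN_NS}}}bbox",
            {
                "x": str(_r(x - ACTIVITY_W / 2)),
                "y": str(_r(y - ACTIVITY_H / 2)),
                "w": str(ACTIVITY_W),
                "h": str(ACTIVITY_H),
            },
        )
    positions = {n.node_id: n.position for n in disease_map.nodes}
    for edge in disease_map.edges:
        arc = ET.SubElement(
            sbgn_map,
            f"{{{SBGN_NS}}}arc",
            {
                "class": ARC_CLASS[edge.edge_class],
                "id": f"arc:{edge.edge_id}",
                "source": edge.source,
                "target": edge.target,
            },
        )
        ext = ET.SubElement(arc, f"{{{SBGN_NS}}}extension")
        ET.SubElement(
            ext,
            f"{{{EXTENSION_NS}}}edgeClass",
            {"category": edge.edge_class.value, "weight": str(edge.weight)},
        )
        sx, sy = positions[edge.source]
        tx, ty = positions[edge.target]
        ET.SubElement(arc, f"{{{SBGN_NS}}}start", {"x": str(_r(sx)), "y": str(_r(sy))})
        ET.SubElement(arc, f"{{{SBGN_NS}}}end", {"x": str(_r(tx)), "y": str(_r(ty))})
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def save(text: str, path: str | Path) -> Path:
    """Write a serialized document to disk (UTF-8)."""
    path = Path(path)
    path.write_text(text, encoding="utf-8")
    return path
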