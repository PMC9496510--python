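"""Disease-map graph model: evidence aggregation and cellular layout.

All sentence-level evidence rows sharing a directed (source, target) pair
are merged into one :class:`InteractionEdge`.  The edge's weight is the
number of *distinct* publications (PubMed IDs) supporting it — the quantity
a viewer renders as edge thickness — and its class is the aggregate of the
per-sentence categories, with conflicting directional evidence yielding the
``incoherent`` class.

The layout is a deterministic banded grid: compartments become vertically
stacked horizontal bands in canonical cellular order (extracellular at the
top, nucleus at the bottom), and each band holds its nodes on a regular
grid.  Determinism — same input, same config, same coordinates — is a
deliberate property: it makes serialized maps diffable and testable.
Coordinates follow the screen convention of browser graph renderers:
x rightward, y downward, origin top-left, float layout units.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from enum import Enum

from .categorize import EvidenceRecord, InteractionCategory, aggregate_categories
from .ingest import EntityRow, InteractionRow

TOOL_VERSION = "0.1.0"


class ReviewStatus(str, Enum):
    UNREVIEWED = "unreviewed"
    ACCEPTED = "accepted"
    DECLINED = "declined"
    FURTHER_INSPECTION_NEEDED = "further_inspection_needed"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class Rect:
    x: float = 0.0
    y: float = 0.0
    width: float = 0.0
    height: float = 0.0


@dataclass(frozen=True)
class Compartment:
    compartment_id: str
    label: str
    bounds: Rect = field(default_factory=Rect)


@dataclass(frozen=True)
class MapNode:
    node_id: str
    label: str
    parent: str  # compartment_id
    position: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class InteractionEdge:
    edge_id: str
    source: str
    target: str
    edge_class: InteractionCategory
    evidences: tuple[EvidenceRecord, ...]
    weight: int
    review_status: ReviewStatus = ReviewStatus.UNREVIEWED

    def __post_init__(self) -> None:
        if not self.evidences:
            raise ValueError(f"edge {self.edge_id}: evidence list must be non-empty")

    @property
    def pmids(self) -> set[int]:
        return {e.pmid for e in self.evidences}


@dataclass
class DiseaseMap:
    """Compartments + entity nodes + aggregated interaction edges.

    ``meta`` carries provenance (creation time, source file names, lexicon
    identity, tool version) and the review audit trail.
    """

    compartments: list[Compartment] = field(default_factory=list)
    nodes: list[MapNode] = field(default_factory=list)
    edges: list[InteractionEdge] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def compartment_by_id(self, cid: str) -> Compartment:
        for c in self.compartments:
            if c.compartment_id == cid:
                return c
        raise KeyError(cid)

    def node_by_id(self, nid: str) -> MapNode:
        for n in self.nodes:
            if n.node_id == nid:
                return n
        raise KeyError(nid)

    def edge_by_id(self, eid: str) -> InteractionEdge:
        for e in self.edges:
            if e.edge_id == eid:
                return e
        raise KeyError(eid)

    @property
    def has_layout(self) -> bool:
        if len(self.nodes) <= 1:
            return True
        return any(n.position != (0.0, 0.0) for n in self.nodes)

    def with_edges(self, edges: list[InteractionEdge]) -> "DiseaseMap":
        """Copy of this map with a replaced edge list (meta deep-copied)."""
        return DiseaseMap(
            compartments=list(self.compartments),
            nodes=list(self.nodes),
            edges=edges,
            meta=copy.deepcopy(self.meta),
        )


def compartment_id_for(name: str) -> str:
    return f"compartment:{name}"


def make_edge(
    source: str,
    target: str,
    evidences: tuple[EvidenceRecord, ...],
    review_status: ReviewStatus = ReviewStatus.UNREVIEWED,
) -> InteractionEdge:
    """Build an edge with class and weight derived from its evidence."""
    return InteractionEdge(
        edge_id=f"{source}->{target}",
        source=source,
        target=target,
        edge_class=aggregate_categories(e.evidence_category for e in evidences),
        evidences=evidences,
        weight=len({e.pmid for e in evidences}),
        review_status=review_status,
    )


def build_map(
    entities: list[EntityRow],
    evidences: list[tuple[InteractionRow, EvidenceRecord]],
    *,
    sources: list[str] | None = None,
    lexicon_name: str | None = None,
    created: str | None = None,
) -> DiseaseMap:
    """Aggregate validated records into a disease map.

    One node per entity, one compartment per distinct compartment name, and
    one edge per directed (source, target) pair carrying every evidence row
    observed for that pair.  Positions stay at the origin until
    :func:`assign_layout` runs.

    ``created`` is an injectable timestamp (ISO-8601) so exports can be
    reproduced byte-for-byte; it defaults to the current UTC time.
    """
    comp_names: list[str] = []
    for ent in entities:
        if ent.compartment not in comp_names:
            comp_names.append(ent.compartment)
    compartments = [Compartment(compartment_id_for(n), n) for n in comp_names]
    nodes = [
        MapNode(e.entity_id, e.label, compartment_id_for(e.compartment))
        for e in entities
    ]
    grouped: dict[tuple[str, str], list[EvidenceRecord]] = {}
    for row, ev in evidences:
        grouped.setdefault((row.source_id, row.target_id), []).append(ev)
    edges = [
        make_edge(src, tgt, tuple(evs)) for (src, tgt), evs in grouped.items()
    ]
    if created is None:
        created = datetime.now(timezone.utc).isoformat(timespec="seconds")
    meta = {
        "created": created,
        "sources": list(sources or []),
        "lexicon": lexicon_name or "unknown",
        "tool_version": TOOL_VERSION,
        "review_audit": [],
    }
    return DiseaseMap(compartments=compartments, nodes=nodes, edges=edges, meta=meta)


#: Canonical top-to-bottom band order of a cell-like layout.  Unknown
#: compartments are appended alphabetically below the nucleus.
CANONICAL_COMPARTMENT_ORDER = (
    "extracellular",
    "plasma membrane",
    "membrane",
    "cytoplasm",
    "endoplasmic reticulum",
    "golgi apparatus",
    "mitochondrion",
    "endosome",
    "lysosome",
    "nucleus",
)


@dataclass(frozen=True)
class LayoutConfig:
    """Banded-grid layout parameters, in layout units (screen pixels).

    ``spacing`` is the grid pitch between node centres; ``margin`` is the
    inset between a band's border and its outermost grid positions, so any
    positive margin guarantees strict containment.
    """

    spacing: float = 80.0
    margin: float = 40.0
    band_gap: float = 10.0
    compartment_order: tuple[str, ...] = CANONICAL_COMPARTMENT_ORDER


def _band_rank(label: str, order: tuple[str, ...]) -> tuple[int, str]:
    try:
        return (order.index(label.lower()), label)
    except ValueError:
        return (len(order), label.lower())


def assign_layout(disease_map: DiseaseMap, config: LayoutConfig = LayoutConfig()) -> DiseaseMap:
    """Place compartments as stacked bands and nodes on per-band grids.

    Bands share a common width (the widest band's) so the map reads as one
    cell.  Within a band, nodes are sorted by (label, id) and filled
    row-major onto a near-square grid; a band with more nodes simply grows,
    it never overflows.  The function is pure and deterministic.
    """
    ranked = sorted(
        disease_map.compartments,
        key=lambda c: _band_rank(c.label, config.compartment_order),
    )
    members: dict[str, list[MapNode]] = {c.compartment_id: [] for c in disease_map.compartments}
    for node in disease_map.nodes:
        members[node.parent].append(node)

    # per-band grid shape and required size
    dims: dict[str, tuple[int, int]] = {}
    for comp in ranked:
        n = len(members[comp.compartment_id])
        ncols = max(1, math.ceil(math.sqrt(n))) if n else 1
        nrows = max(1, math.ceil(n / ncols)) if n else 1
        dims[comp.compartment_id] = (ncols, nrows)
    width = max(
        2 * config.margin + (dims[c.compartment_id][0] - 1) * config.spacing
        for c in ranked
    ) if ranked else 0.0

    new_comps: list[Compartment] = []
    positions: dict[str, tuple[float, float]] = {}
    y = 0.0
    for comp in ranked:
        ncols, nrows = dims[comp.compartment_id]
        height = 2 * config.margin + (nrows - 1) * config.spacing
        bounds = Rect(0.0, y, width, height)
        new_comps.append(replace(comp, bounds=bounds))
        for i, node in enumerate(
            sorted(members[comp.compartment_id], key=lambda n: (n.label, n.node_id))
        ):
            row, col = divmod(i, ncols)
            positions[node.node_id] = (
                config.margin + col * config.spacing,
                y + config.margin + row * config.spacing,
            )
        y += height + config.band_gap
    new_nodes = [replace(n, position=positions[n.node_id]) for n in disease_map.nodes]
    return DiseaseMap(
        compartments=new_comps,
        nodes=new_nodes,
        edges=list(disease_map.edges),
        meta=copy.deepcopy(disease_map.meta),
    )


def validate_map(disease_map: DiseaseMap, check_layout: bool = False) -> list[str]:
    """Structural invariant check; returns a list of violation messages."""
    problems: list[str] = []
    comp_ids = {c.compartment_id for c in disease_map.compartments}
    if len(comp_ids) != len(disease_map.compartments):
        problems.append("duplicate compartment ids")
    node_ids = {n.node_id for n in disease_map.nodes}
    if len(node_ids) != len(disease_map.nodes):
        problems.append("duplicate node ids")
    for n in disease_map.nodes:
        if n.parent not in comp_ids:
            problems.append(f"node {n.node_id}: unknown compartment {n.parent}")
    seen_pairs: set[tuple[str, str]] = set()
    for e in disease_map.edges:
        if e.source not in node_ids or e.target not in node_ids:
            problems.append(f"edge {e.edge_id}: dangling endpoint")
        if (e.source, e.target) in seen_pairs:
            problems.append(f"edge {e.edge_id}: duplicate directed pair")
        seen_pairs.add((e.source, e.target))
        if e.weight != len(e.pmids) or e.weight < 1:
            problems.append(f"edge {e.edge_id}: weight {e.weight} != distinct pmids")
        expected = aggregate_categories(ev.evidence_category for ev in e.evidences)
        if e.edge_class is not expected:
            problems.append(f"edge {e.edge_id}: class {e.edge_class} != {expected}")
    if check_layout:
        comps = {c.compartment_id: c for c in disease_map.compartments}
        for n in disease_map.nodes:
            b = comps[n.parent].bounds if n.parent in comps else Rect()
            x, y = n.position
            if not (b.x < x < b.x + b.width and b.y < y < b.y + b.height):
                problems.append(f"node {n.node_id}: position outside compartment bounds")
    return problems
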