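"""Filtering, timeline snapshots, and the expert review workflow.

These operations are pure: each returns a new :class:`DiseaseMap`, leaving
the input untouched, so a curation session can branch and compare views
(e.g. a filtered map against the full map) without bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone

from .categorize import InteractionCategory
from .mapmodel import DiseaseMap, InteractionEdge, ReviewStatus, make_edge


@dataclass(frozen=True)
class EdgeFilter:
    """Edge visibility filter: by class and by minimum publication count.

    An empty ``allowed_classes`` set means every class is allowed (the
    identity filter on class), matching a viewer whose checkboxes all
    start ticked.
    """

    allowed_classes: frozenset[InteractionCategory] = frozenset()
    min_publications: int = 1

    def __post_init__(self) -> None:
        if self.min_publications < 1:
            raise ValueError("min_publications must be >= 1")

    def matches(self, edge: InteractionEdge) -> bool:
        if self.allowed_classes and edge.edge_class not in self.allowed_classes:
            return False
        return edge.weight >= self.min_publications


@dataclass(frozen=True)
class ReviewDecision:
    """One expert verdict on one edge; never 'unreviewed'."""

    edge_id: str
    status: ReviewStatus
    note: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.status is ReviewStatus.UNREVIEWED:
            raise ValueError("a review decision must set a definite status")


def filter_edges(disease_map: DiseaseMap, edge_filter: EdgeFilter) -> DiseaseMap:
    """Keep exactly the edges matching the filter.

    Nodes and compartments are unchanged — isolated nodes survive, because
    hiding them is a viewer concern, not a data one.
    """
    return disease_map.with_edges(
        [e for e in disease_map.edges if edge_filter.matches(e)]
    )


def snapshot_by_year(disease_map: DiseaseMap, year: int) -> DiseaseMap:
    """The state of knowledge at the end of ``year`` (cumulative cutoff).

    Each edge keeps only evidence published in or before the cutoff year;
    edges left with no evidence are dropped, and weight and class are
    recomputed from the surviving evidence — so an interaction reported as
    activating early and inhibiting later reads as ``activate`` before the
    later publication and ``incoherent`` after it.  Review statuses carry
    over unchanged.
    """
    edges: list[InteractionEdge] = []
    for e in disease_map.edges:
        kept = tuple(ev for ev in e.evidences if ev.year <= year)
        if not kept:
            continue
        edges.append(make_edge(e.source, e.target, kept, review_status=e.review_status))
    return disease_map.with_edges(edges)


def snapshot_series(
    disease_map: DiseaseMap, start: int, end: int, step: int = 5
) -> list[tuple[int, DiseaseMap]]:
    """Cumulative snapshots at ``start, start+step, ..., end`` inclusive."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    if step < 1:
        raise ValueError("step must be >= 1")
    return [
        (year, snapshot_by_year(disease_map, year))
        for year in range(start, end + 1, step)
    ]


def apply_review(disease_map: DiseaseMap, decision: ReviewDecision) -> DiseaseMap:
    """Set an edge's review status; the decision joins the audit trail.

    Last write wins on the edge's current status, but every decision is
    appended to ``meta["review_audit"]`` so collaborative sessions keep a
    full history.  Topology, weights and classes are untouched.
    """
    ids = {e.edge_id for e in disease_map.edges}
    if decision.edge_id not in ids:
        raise KeyError(f"unknown edge {decision.edge_id!r}")
    timestamp = decision.timestamp or datetime.now(timezone.utc).isoformat(
        timespec="seconds"
    )
    new_edges = [
        replace(e, review_status=decision.status) if e.edge_id == decision.edge_id else e
        for e in disease_map.edges
    ]
    result = disease_map.with_edges(new_edges)
    result.meta.setdefault("review_audit", []).append(
        {
            "edge_id": decision.edge_id,
            "status": decision.status.value,
            "note": decision.note,
            "timestamp": timestamp,
        }
    )
    return result


def next_unreviewed(disease_map: DiseaseMap, after: str | None = None) -> str | None:
    """The next unreviewed edge id in stable (sorted-by-id) cyclic order.

    With ``after`` given, iteration continues past that id and wraps around;
    returns ``None`` once every edge carries a definite status.
    """
    unreviewed = sorted(
        e.edge_id
        for e in disease_map.edges
        if e.review_status is ReviewStatus.UNREVIEWED
    )
    if not unreviewed:
        return None
    if after is None:
        return unreviewed[0]
    later = [eid for eid in unreviewed if eid > after]
    return later[0] if later else unreviewed[0]


def review_summary(disease_map: DiseaseMap) -> dict[str, int]:
    """Count edges per review status; values sum to the edge count."""
    counts = {status.value: 0 for status in ReviewStatus}
    for e in disease_map.edges:
        counts[e.review_status.value] += 1
    return counts
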