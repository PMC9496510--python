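"""Serialization: map JSON round trips, review CSV, SBGN-ML output."""

from __future__ import annotations

import json

import pytest
from lxml import etree

import evimap as em
from evimap.exporter import map_to_elements

from conftest import build_from_config, build_from_rows, row

C = em.InteractionCategory
S = em.ReviewStatus
SBGN_NS = "http://sbgn.org/libsbgn/0.2"


class TestMapJson:
    def test_minimal_map_two_node_elements(self):
        m = build_from_rows([em.EntityRow("E1", "A", "cytoplasm")], [])
        doc = json.loads(em.to_map_json(m))
        assert len(doc["elements"]) == 2
        comp, node = doc["elements"]
        assert comp["group"] == node["group"] == "nodes"
        assert node["data"]["parent"] == comp["data"]["id"]

    def test_edge_element_carries_class_and_references(self, two_entities):
        m = build_from_rows(two_entities, [row("E1", "E2", 1, verbs=("activates",))])
        edge = json.loads(em.to_map_json(m))["elements"][-1]
        assert edge["group"] == "edges" and edge["classes"] == "activate"
        assert len(edge["data"]["references"]) >= 1
        ref = edge["data"]["references"][0]
        assert set(ref) == {"pmid", "year", "sentence", "verbs", "verb_categories", "category"}

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_field_equality_and_byte_identity(self, tmp_path, seed):
        m, _, _ = build_from_config(
            tmp_path, em.SynthConfig(n_entities=15, n_edges=30, seed=seed)
        )
        text = em.to_map_json(m)
        m2 = em.from_map_json(text)
        assert m2 == m
        assert em.to_map_json(m2) == text

    def test_round_trip_preserves_review_state_and_audit(self, tmp_path):
        m, _, _ = build_from_config(tmp_path, em.SynthConfig(seed=1))
        eid = sorted(e.edge_id for e in m.edges)[0]
        m = em.apply_review(
            m, em.ReviewDecision(eid, S.ACCEPTED, note="checked", timestamp="2022-09-10T12:00:00+00:00")
        )
        m2 = em.from_map_json(em.to_map_json(m))
        assert m2.edge_by_id(eid).review_status is S.ACCEPTED
        assert m2.meta["review_audit"] == m.meta["review_audit"]

    def test_reference_count_conservation(self, tmp_path):
        m, report, _ = build_from_config(tmp_path, em.SynthConfig(seed=2))
        doc = json.loads(em.to_map_json(m))
        n_refs = sum(
            len(el["data"]["references"])
            for el in doc["elements"]
            if el["group"] == "edges"
        )
        assert n_refs == report.n_interaction_rows

    def test_refuses_export_without_layout(self, two_entities):
        m = build_from_rows(two_entities, [row("E1", "E2", 1)], layout=False)
        with pytest.raises(em.ExportError, match="assign_layout"):
            em.to_map_json(m)
        with pytest.raises(em.ExportError, match="assign_layout"):
            em.to_sbgnml(m)

    def test_dangling_edge_source_error_names_the_edge(self, two_entities):
        m = build_from_rows(two_entities, [row("E1", "E2", 1)])
        doc = map_to_elements(m)
        doc["elements"][-1]["data"]["source"] = "E9"
        with pytest.raises(em.ExportError, match="E1->E2"):
            em.from_map_json(doc)

    def test_missing_key_error_is_located(self, two_entities):
        m = build_from_rows(two_entities, [row("E1", "E2", 1)])
        doc = map_to_elements(m)
        del doc["elements"][-1]["data"]["review_status"]
        with pytest.raises(em.ExportError, match="review_status"):
            em.from_map_json(doc)

    def test_empty_element_list_is_a_valid_empty_map(self):
        m = build_from_rows([], [])
        m2 = em.from_map_json(em.to_map_json(m))
        assert m2.compartments == [] and m2.nodes == [] and m2.edges == []

    def test_positions_have_two_decimal_precision(self, tmp_path):
        m, _, _ = build_from_config(tmp_path, em.SynthConfig(seed=3))
        doc = json.loads(em.to_map_json(m))
        for el in doc["elements"]:
            if el["group"] == "nodes":
                for v in el["position"].values():
                    assert round(v, 2) == v

    def test_every_export_validates_against_packaged_schema(self, tmp_path):
        from evimap.schema_validator import validate

        schema = em.load_schema()
        m, _, _ = build_from_config(tmp_path, em.SynthConfig(seed=6))
        assert validate(map_to_elements(m), schema) == []


class TestReviewCsv:
    def test_statuses_and_line_count(self, two_entities):
        m = build_from_rows(
            two_entities, [row("E1", "E2", 1), row("E2", "E1", 2)]
        )
        m = em.apply_review(m, em.ReviewDecision("E1->E2", S.ACCEPTED))
        lines = em.to_review_csv(m).splitlines()
        assert len(lines) == 3
        assert lines[0] == "edge_id,source_label,target_label,edge_class,weight,review_status,pmids"
        assert "accepted" in lines[1] and "unreviewed" in lines[2]

    def test_pmids_sorted_ascending(self, two_entities):
        m = build_from_rows(two_entities, [row("E1", "E2", 222), row("E1", "E2", 111)])
        assert em.to_review_csv(m).splitlines()[1].endswith("111;222")

    def test_empty_map_is_header_only(self):
        m = build_from_rows([], [])
        assert em.to_review_csv(m).splitlines() == [
            "edge_id,source_label,target_label,edge_class,weight,review_status,pmids"
        ]

    def test_rows_sorted_by_edge_id(self, tmp_path):
        m, _, _ = build_from_config(tmp_path, em.SynthConfig(seed=7))
        ids = [line.split(",")[0] for line in em.to_review_csv(m).splitlines()[1:]]
        assert ids == sorted(ids)


def _parse_sbgn(text: str) -> etree._Element:
    return etree.fromstring(text.encode("utf-8"))


class TestSbgnMl:
    def test_minimal_document_structure(self):
        m = build_from_rows([em.EntityRow("E1", "A", "cytoplasm")], [])
        root = _parse_sbgn(em.to_sbgnml(m))
        assert root.tag == f"{{{SBGN_NS}}}sbgn"
        sbgn_map = root[0]
        assert sbgn_map.get("language") == "activity flow"
        glyphs = sbgn_map.findall(f"{{{SBGN_NS}}}glyph")
        assert [g.get("class") for g in glyphs] == ["compartment", "biological activity"]
        comp_bbox = glyphs[0].find(f"{{{SBGN_NS}}}bbox")
        node_bbox = glyphs[1].find(f"{{{SBGN_NS}}}bbox")
        cx, cy = float(comp_bbox.get("x")), float(comp_bbox.get("y"))
        cw, ch = float(comp_bbox.get("w")), float(comp_bbox.get("h"))
        nx, ny = float(node_bbox.get("x")), float(node_bbox.get("y"))
        nw, nh = float(node_bbox.get("w")), float(node_bbox.get("h"))
        assert cx <= nx and ny >= cy and nx + nw <= cx + cw and ny + nh <= cy + ch

    @pytest.mark.parametrize(
        "verbs,arc_class",
        [
            (("activates",), "stimulation"),
            (("inhibits",), "inhibition"),
            (("binds",), "influence"),
            (("flurbs",), "influence"),
        ],
    )
    def test_edge_class_to_arc_class(self, two_entities, verbs, arc_class):
        m = build_from_rows(two_entities, [row("E1", "E2", 1, verbs=verbs)])
        root = _parse_sbgn(em.to_sbgnml(m))
        arcs = root[0].findall(f"{{{SBGN_NS}}}arc")
        assert [a.get("class") for a in arcs] == [arc_class]

    def test_original_class_preserved_in_extension(self, two_entities):
        rows = [
            row("E1", "E2", 1, verbs=("activates",)),
            row("E1", "E2", 2, verbs=("inhibits",)),
        ]
        m = build_from_rows(two_entities, rows)
        root = _parse_sbgn(em.to_sbgnml(m))
        arc = root[0].find(f"{{{SBGN_NS}}}arc")
        assert arc.get("class") == "influence"
        ext = arc.find(f"{{{SBGN_NS}}}extension")[0]
        assert ext.get("category") == "incoherent" and ext.get("weight") == "2"

    @pytest.mark.parametrize("seed", range(3))
    def test_generated_fixtures_reparse_and_resolve(self, tmp_path, seed):
        """Independent re-parse: references resolve, every arc has endpoints."""
        m, _, _ = build_from_config(tmp_path, em.SynthConfig(seed=seed))
        root = _parse_sbgn(em.to_sbgnml(m))
        sbgn_map = root[0]
        glyph_ids = {g.get("id") for g in sbgn_map.findall(f"{{{SBGN_NS}}}glyph")}
        comp_ids = {
            g.get("id")
            for g in sbgn_map.findall(f"{{{SBGN_NS}}}glyph")
            if g.get("class") == "compartment"
        }
        for g in sbgn_map.findall(f"{{{SBGN_NS}}}glyph"):
            if g.get("class") == "biological activity":
                assert g.get("compartmentRef") in comp_ids
                assert g.find(f"{{{SBGN_NS}}}label") is not None
                assert g.find(f"{{{SBGN_NS}}}bbox") is not None
        arcs = sbgn_map.findall(f"{{{SBGN_NS}}}arc")
        assert len(arcs) == len(m.edges)
        for a in arcs:
            assert a.get("source") in glyph_ids and a.get("target") in glyph_ids
            assert a.find(f"{{{SBGN_NS}}}start") is not None
            assert a.find(f"{{{SBGN_NS}}}end") is not None
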