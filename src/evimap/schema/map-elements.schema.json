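{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "map-elements.schema.json",
  "title": "evimap disease-map elements document",
  "description": "A disease map serialized as provenance metadata plus a flat list of graph elements (compartments and entities as nodes, interactions as edges) in the compound-node convention of browser graph renderers.",
  "type": "object",
  "required": ["meta", "elements"],
  "properties": {
    "meta": {
      "type": "object",
      "required": ["created", "sources", "lexicon", "tool_version", "review_audit"],
      "properties": {
        "created": {"type": "string"},
        "sources": {"type": "array", "items": {"type": "string"}},
        "lexicon": {"type": "string"},
        "tool_version": {"type": "string"},
        "review_audit": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["edge_id", "status", "note", "timestamp"],
            "properties": {
              "edge_id": {"type": "string"},
              "status": {"enum": ["accepted", "declined", "further_inspection_needed"]},
              "note": {"type": "string"},
              "timestamp": {"type": "string"}
            }
          }
        }
      }
    },
    "elements": {
      "type": "array",
      "items": {
        "oneOf": [
          {"$ref": "#/definitions/compartment"},
          {"$ref": "#/definitions/node"},
          {"$ref": "#/definitions/edge"}
        ]
      }
    }
  },
  "definitions": {
    "position": {
      "type": "object",
      "required": ["x", "y"],
      "properties": {"x": {"type": "number"}, "y": {"type": "number"}},
      "additionalProperties": false
    },
    "compartment": {
      "type": "object",
      "required": ["group", "data", "position"],
      "properties": {
        "group": {"enum": ["nodes"]},
        "data": {
          "type": "object",
          "required": ["id", "label", "bbox"],
          "properties": {
            "id": {"type": "string"},
            "label": {"type": "string"},
            "bbox": {
              "type": "object",
              "required": ["x", "y", "width", "height"],
              "properties": {
                "x": {"type": "number"},
                "y": {"type": "number"},
                "width": {"type": "number"},
                "height": {"type": "number"}
              },
              "additionalProperties": false
            }
          },
          "additionalProperties": false
        },
        "position": {"$ref": "#/definitions/position"}
      },
      "additionalProperties": false
    },
    "node": {
      "type": "object",
      "required": ["group", "data", "position"],
      "properties": {
        "group": {"enum": ["nodes"]},
        "data": {
          "type": "object",
          "required": ["id", "label", "parent"],
          "properties": {
            "id": {"type": "string"},
            "label": {"type": "string"},
            "parent": {"type": "string"}
          },
          "additionalProperties": false
        },
        "position": {"$ref": "#/definitions/position"}
      },
      "additionalProperties": false
    },
    "edge": {
      "type": "object",
      "required": ["group", "data", "classes"],
      "properties": {
        "group": {"enum": ["edges"]},
        "data": {
          "type": "object",
          "required": ["id", "source", "target", "weight", "review_status", "references"],
          "properties": {
            "id": {"type": "string"},
            "source": {"type": "string"},
            "target": {"type": "string"},
            "weight": {"type": "integer", "minimum": 1},
            "review_status": {
              "enum": ["unreviewed", "accepted", "declined", "further_inspection_needed"]
            },
            "references": {
              "type": "array",
              "minItems": 1,
              "items": {
                "type": "object",
                "required": ["pmid", "year", "sentence", "verbs", "verb_categories", "category"],
                "properties": {
                  "pmid": {"type": "integer", "minimum": 1},
                  "year": {"type": "integer"},
                  "sentence": {"type": "string"},
                  "verbs": {"type": "array", "items": {"type": "string"}},
                  "verb_categories": {
                    "type": "array",
                    "items": {"enum": ["activate", "inhibit", "neutral", "undefined"]}
                  },
                  "category": {"enum": ["activate", "inhibit", "neutral", "undefined"]}
                },
                "additionalProperties": false
              }
            }
          },
          "additionalProperties": false
        },
        "classes": {"enum": ["neutral", "inhibit", "activate", "undefined", "incoherent"]}
      },
      "additionalProperties": false
    }
  }
}
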