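{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "symptomnet analysis report",
  "type": "object",
  "required": ["meta", "descriptives", "prevalence", "network", "centrality"],
  "properties": {
    "meta": {
      "type": "object",
      "required": ["seed", "n", "items"],
      "properties": {
        "seed": {"type": "integer"},
        "n": {"type": "integer"},
        "items": {"type": "array", "items": {"type": "string"}}
      }
    },
    "descriptives": {"type": "array", "items": {"type": "object"}},
    "prevalence": {
      "type": "object",
      "properties": {
        "anxiety": {"$ref": "#/$defs/prevalence"},
        "poor_sleep": {"$ref": "#/$defs/prevalence"},
        "clinical_sleep": {"$ref": "#/$defs/prevalence"}
      }
    },
    "network": {
      "type": "object",
      "required": ["lambda", "gamma", "ebic", "edge_count", "edges"],
      "properties": {
        "lambda": {"type": "number"},
        "gamma": {"type": "number"},
        "ebic": {"type": "number"},
        "edge_count": {"type": "integer"},
        "edges": {"type": "array", "items": {"type": "object"}}
      }
    },
    "centrality": {"type": "array", "items": {"type": "object"}},
    "top_symptoms": {
      "type": "object",
      "properties": {
        "by_ei": {"type": "array", "items": {"type": "string"}},
        "by_bridge_ei": {"type": "array", "items": {"type": "string"}}
      }
    },
    "stability": {"type": "object"},
    "adjusted_comparison": {"type": "object"},
    "nct": {"type": "object"}
  },
  "$defs": {
    "prevalence": {
      "type": "object",
      "required": ["count", "n", "proportion", "ci_low", "ci_high"],
      "properties": {
        "count": {"type": "integer"},
        "n": {"type": "integer"},
        "proportion": {"type": "number"},
        "ci_low": {"type": "number"},
        "ci_high": {"type": "number"}
      }
    }
  }
}
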