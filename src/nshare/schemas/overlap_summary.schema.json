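{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "nshare overlap summary record",
  "type": "object",
  "required": [
    "scope",
    "direction",
    "constraint",
    "n_bar",
    "pairs_included",
    "pairs_excluded_degenerate",
    "pairs_excluded_zero_degree"
  ],
  "properties": {
    "scope": {
      "enum": ["rows", "cols", "both-guilds", "unimode-out", "unimode-in", "unimode-undirected"]
    },
    "direction": {"enum": ["out", "in", "undirected"]},
    "constraint": {"type": ["string", "null"]},
    "n_bar": {"type": ["number", "null"], "minimum": -1, "maximum": 1},
    "n_bar_defined": {"type": "boolean"},
    "pairs_included": {"type": "integer", "minimum": 0},
    "pairs_excluded_degenerate": {"type": "integer", "minimum": 0},
    "pairs_excluded_zero_degree": {"type": "integer", "minimum": 0},
    "trophic_levels": {
      "type": "object",
      "additionalProperties": {"type": ["integer", "null"]}
    },
    "per_pair": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["node_i", "node_j", "n", "d_i", "d_j", "observed", "expected", "s_min", "s_max", "value", "degenerate"],
        "properties": {
          "node_i": {"type": "string"},
          "node_j": {"type": "string"},
          "n": {"type": "integer", "minimum": 0},
          "d_i": {"type": "integer", "minimum": 0},
          "d_j": {"type": "integer", "minimum": 0},
          "observed": {"type": "integer", "minimum": 0},
          "expected": {"type": ["number", "null"]},
          "s_min": {"type": "integer", "minimum": 0},
          "s_max": {"type": "integer", "minimum": 0},
          "value": {"type": ["number", "null"], "minimum": -1, "maximum": 1},
          "degenerate": {"type": "boolean"},
          "reason": {"type": ["string", "null"]}
        }
      }
    }
  }
}
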