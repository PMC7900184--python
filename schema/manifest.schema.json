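{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "immunet run manifest",
  "type": "object",
  "required": ["package_version", "status", "seed", "environment", "networks", "tests"],
  "properties": {
    "package_version": {"type": "string"},
    "status": {"type": "string", "enum": ["OK", "FAILED", "RUNNING"]},
    "seed": {"type": "integer"},
    "environment": {"type": "string"},
    "n_subjects": {"type": "integer"},
    "n_measures": {"type": "integer"},
    "stages": {"type": "array", "items": {"type": "string"}},
    "failed_stage": {"type": "string"},
    "error": {"type": "string"},
    "networks": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["threshold", "n_nodes", "n_edges", "edge_density", "connected"],
        "properties": {
          "threshold": {"type": "number"},
          "n_nodes": {"type": "integer"},
          "n_edges": {"type": "integer"},
          "edge_density": {"type": "number"},
          "connected": {"type": "boolean"},
          "n_communities": {"type": "integer"},
          "n_unassigned": {"type": "integer"},
          "community_sizes": {"type": "object"},
          "intercommunity_densities": {"type": "object"},
          "consensus": {"type": "object"}
        }
      }
    },
    "tests": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["type", "observed", "p_value", "n_null", "seed"]
      }
    },
    "pca": {"type": "array"},
    "truth_partition": {"type": "object"}
  }
}
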