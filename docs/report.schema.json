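{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mabseq workflow report",
  "type": "object",
  "required": ["tool_version", "config", "chains"],
  "properties": {
    "tool_version": {"type": "string"},
    "config": {"type": "object"},
    "chains": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["chain", "n_reads", "clusters"],
        "properties": {
          "chain": {"enum": ["heavy", "kappa", "lambda"]},
          "n_reads": {"type": "integer", "minimum": 1},
          "clusters": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["consensus", "members", "size", "orf", "aberrant"],
              "properties": {
                "consensus": {"type": "string"},
                "members": {"type": "array", "items": {"type": "string"}},
                "size": {"type": "integer", "minimum": 1},
                "orf": {"type": "object"},
                "aberrant": {"type": "boolean"},
                "annotation": {"type": "object"},
                "isotype": {"type": "object"},
                "cdr3_primer": {"type": "object"}
              }
            }
          },
          "error": {"type": ["string", "null"]}
        }
      }
    },
    "isotype": {"type": ["object", "null"]},
    "primers": {"type": "object"},
    "strain_comparison": {"type": "array"},
    "assembly": {"type": "object"},
    "fingerprint": {"type": ["object", "null"]},
    "notes": {"type": "array", "items": {"type": "string"}}
  }
}
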