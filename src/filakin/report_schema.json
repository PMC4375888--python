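{
  "title": "filakin report",
  "type": "object",
  "required": ["schema_version", "seed", "config", "input_hashes", "results"],
  "properties": {
    "schema_version": {"type": "string"},
    "seed": {"type": ["integer", "null"]},
    "config": {"type": "object"},
    "input_hashes": {"type": "object"},
    "results": {"type": "object"}
  }
}
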