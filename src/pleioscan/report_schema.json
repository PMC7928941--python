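{
  "type": "object",
  "required": ["version", "seed", "stages"],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "stages": {"type": "object"}
  }
}
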