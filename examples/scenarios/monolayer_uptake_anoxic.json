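{
  "kind": "monolayer_uptake",
  "options": {
    "line": "activator",
    "oxygen_uM": 0.0,
    "observed_compounds": ["CP-506", "CP-506H", "CP-506M"]
  }
}
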