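{
  "kind": "monolayer_uptake",
  "options": {"line": "activator", "observed_compounds": ["CP-506"]}
}
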