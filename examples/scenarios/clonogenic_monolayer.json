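{
  "kind": "clonogenic",
  "options": {"c0_values_uM": [0.003, 0.01, 0.03, 0.1, 0.3]}
}
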