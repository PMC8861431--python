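{
  "kind": "spheroid_coculture",
  "options": {
    "c0_values_uM": [0.1, 0.3, 1.0],
    "activator_fractions": [0.0, 0.1, 0.5, 1.0],
    "spheroid_radius_um": 50.0
  }
}
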