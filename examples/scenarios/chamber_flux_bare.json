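{
  "kind": "chamber_flux",
  "options": {"condition": "supraoxic", "has_mcl": false, "include_urea": false, "c0_uM": 20.0}
}
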