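{
  "kind": "chamber_flux",
  "options": {
    "condition": "anoxic",
    "has_mcl": true,
    "include_urea": true,
    "c0_uM": 17.4,
    "params": {
      "d_sup_cm2_s": 7.17e-07
    }
  }
}
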