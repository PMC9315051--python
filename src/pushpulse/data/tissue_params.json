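{
  "version": 1,
  "white_matter": {
    "description": "Two-pool white-matter parameters for MT-weighted SPGR simulation",
    "R1f_per_s": 0.4,
    "T2f_s": 0.06,
    "f": 0.1357,
    "k_per_s": 32.79,
    "R1s_per_s": 1.85,
    "lineshape": {
      "kind": "super_lorentzian",
      "T2s_s": 9.6e-6,
      "shift_hz": -773.0
    }
  }
}
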