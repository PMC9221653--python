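{
  "10x10": {"diameter_mm": 10.0, "length_mm": 10.0, "magnetisation_kA_per_m": 1150.0},
  "5x10": {"diameter_mm": 10.0, "length_mm": 5.0, "magnetisation_kA_per_m": 1150.0},
  "3x10": {"diameter_mm": 10.0, "length_mm": 3.0, "magnetisation_kA_per_m": 1150.0}
}
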