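{
  "n_patients": 55,
  "n_hemangiomas": 55,
  "n_with_variation": 48,
  "mean_delta_t_c": 0.20,
  "ci90_c": [0.16, 0.25]
}
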