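{
  "description": "Descending per-metric frequency orderings (breaths/min) for one recorded stepped assessment; the reference decision is 4.5.",
  "orderings": {
    "mean_amp": [4.5, 5.0, 5.5, 6.0, 6.5],
    "lf_ratio": [4.5, 5.0, 6.0, 6.5, 5.5],
    "plv": [4.5, 5.0, 6.5, 6.0, 5.5]
  },
  "expected_rf": 4.5
}
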