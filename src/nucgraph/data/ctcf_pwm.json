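{
  "name": "ctcf-core-synthetic",
  "comment": "Constructed (synthetic) position probability matrix around the canonical CTCF zinc-finger core consensus CCGCGNGGNGGCAG: consensus base 0.85, other bases 0.05, degenerate N positions uniform. Not a database motif export.",
  "threshold_fraction": 0.8,
  "alphabet": "ACGT",
  "probabilities": [
    [0.05, 0.85, 0.05, 0.05],
    [0.05, 0.85, 0.05, 0.05],
    [0.05, 0.05, 0.85, 0.05],
    [0.05, 0.85, 0.05, 0.05],
    [0.05, 0.05, 0.85, 0.05],
    [0.25, 0.25, 0.25, 0.25],
    [0.05, 0.05, 0.85, 0.05],
    [0.05, 0.05, 0.85, 0.05],
    [0.25, 0.25, 0.25, 0.25],
    [0.05, 0.05, 0.85, 0.05],
    [0.05, 0.05, 0.85, 0.05],
    [0.05, 0.85, 0.05, 0.05],
    [0.85, 0.05, 0.05, 0.05],
    [0.05, 0.05, 0.85, 0.05]
  ]
}
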