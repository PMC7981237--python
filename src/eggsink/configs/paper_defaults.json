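{
  "a1": 1.0,
  "a2": 0.45,
  "r1": 2.0,
  "r2": 2.0,
  "K1": 1000.0,
  "K2": 1000.0,
  "s1": 1.0,
  "s2": 0.0,
  "mu1": 0.0,
  "mu2": 0.4,
  "beta": 16.0,
  "k": 0.75,
  "X": 0.29
}
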