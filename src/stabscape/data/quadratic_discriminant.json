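{
  "name": "quadratic_discriminant",
  "variables": ["x"],
  "parameters": ["a1", "a2", "a3"],
  "rates": ["a1*x^2 + a2*x + a3"]
}
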