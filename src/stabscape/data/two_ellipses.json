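{
  "name": "two_ellipses",
  "parameters": ["a1", "a2"],
  "polynomials": [
    "(a1 - 5)^2 + 4*(a2 - 5)^2 - 16",
    "4*(a1 - 5)^2 + (a2 - 5)^2 - 16"
  ]
}
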