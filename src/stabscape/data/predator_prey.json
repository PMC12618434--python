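{
  "name": "predator_prey",
  "variables": ["x", "y"],
  "parameters": ["alpha", "beta", "gamma", "m", "K", "A"],
  "rates": [
    "x*(1 - x/K)*(x/A - 1) - alpha*x*y/(1 + beta*x)",
    "y*(-m + gamma*x/(1 + beta*x))"
  ]
}
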