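{
  "name": "levins_culver",
  "variables": ["y", "z"],
  "parameters": ["beta_y", "beta_z", "gamma_y", "gamma_z"],
  "rates": [
    "beta_y*y*(1 - y) - gamma_y*y",
    "beta_z*z*(1 - y - z) - beta_y*y*z - gamma_z*z"
  ]
}
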