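{
  "name": "coral",
  "variables": ["x", "y", "z"],
  "parameters": ["b", "btilde", "beta_y", "beta_z", "d", "dtilde", "gamma_y", "gamma_z"],
  "rates": [
    "(b*(x + y) + (b + btilde)*z)*(1 - (x + y + z)) - beta_y*x*y - beta_z*x*z + gamma_y*y + gamma_z*z - d*x",
    "beta_y*x*y + beta_y*y*z - (d + dtilde + gamma_y)*y",
    "beta_z*x*z - beta_y*y*z - (d + gamma_z)*z"
  ]
}
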