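{
  "name": "illustration",
  "meta": {
    "description": "Four-pool illustration network: two parallel input branches joined by one cytosol/ER diffusion pair, two flux split ratios (A1 at X2, A2 at X4)."
  },
  "metabolites": [
    {"id": "X1", "name": "upstream pool, branch 1", "compartment": "cytosol", "roles": ["input_pool"]},
    {"id": "X2", "name": "diffusing species, cytosol pool", "compartment": "cytosol", "species": "X24"},
    {"id": "X3", "name": "upstream pool, branch 2", "compartment": "cytosol", "roles": ["input_pool"]},
    {"id": "X4", "name": "diffusing species, ER pool", "compartment": "ER", "species": "X24"}
  ],
  "fluxes": [
    {"id": "VIN1", "kind": "input", "products": [["X1", 1]], "value": 100.0},
    {"id": "VIN2", "kind": "input", "products": [["X3", 1]], "value": 100.0},
    {"id": "V1", "kind": "enzymatic", "substrates": [["X1", 1]], "products": [["X2", 1]]},
    {"id": "V2", "kind": "efflux", "substrates": [["X2", 1]]},
    {"id": "V3", "kind": "enzymatic", "substrates": [["X3", 1]], "products": [["X4", 1]]},
    {"id": "D", "kind": "diffusion_net", "substrates": [["X2", 1]], "products": [["X4", 1]]},
    {"id": "V4", "kind": "efflux", "substrates": [["X4", 1]]},
    {"id": "V5", "kind": "efflux", "substrates": [["X4", 1]]}
  ]
}
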