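{
  "name": "brachy_fig4",
  "meta": {
    "description": "Baseline compartmental lignin pathway of Brachypodium distachyon: ER-bound C4H/C3'H/F5H steps, cytosolic everything else, no ER-side 4CL/C3H activity and no metabolic channel. Flux ids are local to this package and provisional with respect to the source figures.",
    "notes": [
      "Single-source monomolecular chains that cross a compartment boundary are lumped into one edge (PAL+C4H; F5H+COMT+CAD); the lumping is label-neutral because both pools of such a chain provably carry the source label.",
      "The cytosolic C3H conversion of p-coumaric acid to caffeic acid (edge V4) is speculative in this organism and can be removed with PathwayNetwork.without_edges."
    ]
  },
  "metabolites": [
    {"id": "PHE", "name": "phenylalanine", "compartment": "cytosol", "roles": ["input_pool"]},
    {"id": "TYR", "name": "tyrosine", "compartment": "cytosol", "roles": ["input_pool"]},
    {"id": "PCA_e", "name": "p-coumaric acid (ER)", "compartment": "ER", "species": "p-coumaric acid"},
    {"id": "PCA_c", "name": "p-coumaric acid (cytosol)", "compartment": "cytosol", "species": "p-coumaric acid", "roles": ["wall_coumaric"]},
    {"id": "CAF_c", "name": "caffeic acid (cytosol)", "compartment": "cytosol", "species": "caffeic acid"},
    {"id": "FER_c", "name": "ferulic acid (cytosol)", "compartment": "cytosol", "species": "ferulic acid", "roles": ["wall_ferulic"]},
    {"id": "PCCOA_c", "name": "p-coumaroyl-CoA (cytosol)", "compartment": "cytosol", "species": "p-coumaroyl-CoA"},
    {"id": "HALC_c", "name": "p-coumaryl alcohol", "compartment": "cytosol", "species": "p-coumaryl alcohol", "roles": ["H_sink"]},
    {"id": "FCOA_c", "name": "feruloyl-CoA (cytosol)", "compartment": "cytosol", "species": "feruloyl-CoA"},
    {"id": "CALD_c", "name": "coniferaldehyde (cytosol)", "compartment": "cytosol", "species": "coniferaldehyde"},
    {"id": "CALD_e", "name": "coniferaldehyde (ER)", "compartment": "ER", "species": "coniferaldehyde"},
    {"id": "CALC_c", "name": "coniferyl alcohol (cytosol)", "compartment": "cytosol", "species": "coniferyl alcohol", "roles": ["G_sink"]},
    {"id": "SALC_c", "name": "sinapyl alcohol", "compartment": "cytosol", "species": "sinapyl alcohol", "roles": ["S_sink"]}
  ],
  "fluxes": [
    {"id": "IN_PHE", "kind": "input", "products": [["PHE", 1]], "value": 100.0},
    {"id": "IN_TYR", "kind": "input", "products": [["TYR", 1]], "value": 100.0},
    {"id": "V1", "kind": "enzymatic", "enzyme": "PAL/C4H", "substrates": [["PHE", 1]], "products": [["PCA_e", 1]]},
    {"id": "V2", "kind": "enzymatic", "enzyme": "TAL", "substrates": [["TYR", 1]], "products": [["PCA_c", 1]]},
    {"id": "D2", "kind": "diffusion_net", "substrates": [["PCA_e", 1]], "products": [["PCA_c", 1]]},
    {"id": "V3", "kind": "enzymatic", "enzyme": "4CL", "substrates": [["PCA_c", 1]], "products": [["PCCOA_c", 1]]},
    {"id": "V4", "kind": "enzymatic", "enzyme": "C3H", "substrates": [["PCA_c", 1]], "products": [["CAF_c", 1]]},
    {"id": "V5", "kind": "efflux", "substrates": [["PCA_c", 1]]},
    {"id": "V6", "kind": "enzymatic", "enzyme": "COMT", "substrates": [["CAF_c", 1]], "products": [["FER_c", 1]]},
    {"id": "V7", "kind": "enzymatic", "enzyme": "4CL", "substrates": [["FER_c", 1]], "products": [["FCOA_c", 1]]},
    {"id": "V9", "kind": "efflux", "substrates": [["FER_c", 1]]},
    {"id": "V10", "kind": "enzymatic", "enzyme": "CCR/CAD", "substrates": [["PCCOA_c", 1]], "products": [["HALC_c", 1]]},
    {"id": "V11", "kind": "enzymatic", "enzyme": "HCT/C3'H/CCoAOMT", "substrates": [["PCCOA_c", 1]], "products": [["FCOA_c", 1]]},
    {"id": "V22", "kind": "enzymatic", "enzyme": "CCR", "substrates": [["FCOA_c", 1]], "products": [["CALD_c", 1]]},
    {"id": "V23", "kind": "enzymatic", "enzyme": "CAD", "substrates": [["CALD_c", 1]], "products": [["CALC_c", 1]]},
    {"id": "D5", "kind": "diffusion_net", "substrates": [["CALD_c", 1]], "products": [["CALD_e", 1]]},
    {"id": "V25", "kind": "enzymatic", "enzyme": "F5H/COMT/CAD", "substrates": [["CALD_e", 1]], "products": [["SALC_c", 1]]},
    {"id": "EH", "kind": "efflux", "substrates": [["HALC_c", 1]]},
    {"id": "EG", "kind": "efflux", "substrates": [["CALC_c", 1]]},
    {"id": "ES", "kind": "efflux", "substrates": [["SALC_c", 1]]}
  ]
}
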