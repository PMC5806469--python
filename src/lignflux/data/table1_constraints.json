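{
  "name": "table1",
  "nonnegative": true,
  "composition": [
    {"observable": "H_frac", "value": 4.0, "tol": 5.0, "mode": "abs"},
    {"observable": "G_frac", "value": 41.0, "tol": 5.0, "mode": "abs"},
    {"observable": "S_frac", "value": 55.0, "tol": 5.0, "mode": "abs"},
    {"observable": "SG_ratio", "value": 1.09, "tol": 0.10, "mode": "rel"}
  ],
  "experiments": [
    {
      "id": "phe",
      "feeding": {"pool": "PHE", "fraction": 0.35},
      "targets": [
        {"observable": "incorporation.G", "value": 22.3, "tol": 5.0, "mode": "abs"},
        {"observable": "incorporation.S", "value": 21.0, "tol": 5.0, "mode": "abs"},
        {"observable": "incorporation.total_lignin", "value": 22.2, "tol": 5.0, "mode": "abs"},
        {"observable": "incorporation.wall_coumaric", "value": 21.0, "tol": 5.0, "mode": "abs"},
        {"observable": "incorporation.wall_ferulic", "value": 23.0, "tol": 5.0, "mode": "abs"}
      ],
      "unused_targets": [
        {"observable": "incorporation.H", "value": 36.0,
         "reason": "measured value exceeds the 35% feed label and was deemed unreliable; H incorporation is not used as a screening criterion"}
      ]
    },
    {
      "id": "tyr",
      "feeding": {"pool": "TYR", "fraction": 0.35},
      "targets": [
        {"observable": "incorporation.G", "value": 16.5, "tol": 5.0, "mode": "abs"},
        {"observable": "incorporation.S", "value": 18.1, "tol": 5.0, "mode": "abs"},
        {"observable": "incorporation.total_lignin", "value": 18.6, "tol": 5.0, "mode": "abs"},
        {"observable": "incorporation.wall_coumaric", "value": 17.0, "tol": 5.0, "mode": "abs"},
        {"observable": "incorporation.wall_ferulic", "value": 13.0, "tol": 5.0, "mode": "abs"}
      ],
      "unused_targets": [
        {"observable": "incorporation.H", "value": 24.6,
         "reason": "H incorporation is not used as a screening criterion in either feeding experiment (the companion phe measurement is unreliable and H is a minor monomer)"}
      ]
    }
  ]
}
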