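{
  "comment": "Published reference values and reconstruction tolerances for the reproduce command. Tolerances reflect that the published figures come from rounded values and unstated curve-fitting software settings.",
  "checks": {
    "r2_ddh_vs_anim": {"expected": 0.99756, "tol": 0.002},
    "anim_at_ddh70": {"expected": 96.7, "tol": 0.3},
    "mlsa_at_ddh70": {"expected": 0.008, "tol": 0.003},
    "count_mlsa_ge_0.008_ddh_gt_70": {"expected": 7, "tol": 0},
    "count_mlsa_ge_0.007_ddh_lt_70_anim_gt_96": {"expected": 4, "tol": 0},
    "count_mlsa_in_0.008_0.014_ddh_lt_70": {"expected": 9, "tol": 0},
    "record_count": {"expected": 80, "tol": 0},
    "borderline_count": {"expected": 5, "tol": 0}
  },
  "emendation_pairs": [
    ["antimycoticus", "melanosporofaciens"],
    ["filipinensis", "durhamensis"],
    ["recifensis", "griseoluteus"],
    ["olivaceoviridis", "corchorusii"]
  ]
}
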