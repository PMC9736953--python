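{
  "version": "dlcn-standard-1",
  "groups": {
    "family_history": {
      "first_degree_xanthoma_arcus_or_child_high_ldl": 2,
      "first_degree_premature_cad_or_high_ldl": 1
    },
    "clinical_history": {
      "personal_premature_cad": 2,
      "personal_premature_cerebral_or_peripheral": 1
    },
    "physical_exam": {
      "tendon_xanthomata": 6,
      "premature_corneal_arcus": 4
    },
    "ldl_bands": [
      {"lower": 8.5, "upper": null, "points": 8},
      {"lower": 6.5, "upper": 8.5, "points": 5},
      {"lower": 5.0, "upper": 6.5, "points": 3},
      {"lower": 4.0, "upper": 5.0, "points": 1}
    ],
    "dna": {
      "pathogenic_variant": 8
    }
  },
  "premature_corneal_arcus_age_max": 45,
  "categories": {
    "possible_min": 3,
    "probable_min": 6,
    "definite_min": 9
  }
}
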