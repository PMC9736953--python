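{
  "version": "acmg-amp-2015",
  "comment": "Evidence-combination clauses. Each clause lists minimum code counts per strength class (PVS very strong, PS strong, PM moderate, PP supporting; BA stand-alone benign, BS strong benign, BP supporting benign). Within each tier the first matching clause, in list order, is reported as the fired rule. Pathogenic clauses are checked before likely-pathogenic, benign before likely-benign. A match on both the pathogenic and the benign side is conflicting evidence and yields VUS.",
  "pathogenic": [
    {"rule": "P.1a", "min": {"PVS": 1, "PS": 1}},
    {"rule": "P.1b", "min": {"PVS": 1, "PM": 2}},
    {"rule": "P.1c", "min": {"PVS": 1, "PM": 1, "PP": 1}},
    {"rule": "P.1d", "min": {"PVS": 1, "PP": 2}},
    {"rule": "P.2",  "min": {"PS": 2}},
    {"rule": "P.3a", "min": {"PS": 1, "PM": 3}},
    {"rule": "P.3b", "min": {"PS": 1, "PM": 2, "PP": 2}},
    {"rule": "P.3c", "min": {"PS": 1, "PM": 1, "PP": 4}}
  ],
  "likely_pathogenic": [
    {"rule": "LP.1", "min": {"PVS": 1, "PM": 1}},
    {"rule": "LP.2", "min": {"PS": 1, "PM": 1}},
    {"rule": "LP.3", "min": {"PS": 1, "PP": 2}},
    {"rule": "LP.4", "min": {"PM": 3}},
    {"rule": "LP.5", "min": {"PM": 2, "PP": 2}},
    {"rule": "LP.6", "min": {"PM": 1, "PP": 4}}
  ],
  "benign": [
    {"rule": "B.1", "min": {"BA": 1}},
    {"rule": "B.2", "min": {"BS": 2}}
  ],
  "likely_benign": [
    {"rule": "LB.1", "min": {"BS": 1, "BP": 1}},
    {"rule": "LB.2", "min": {"BP": 2}}
  ]
}
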