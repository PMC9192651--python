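{
  "comment": "Per-diagnosis-group marginal counts for the 16 risk factors in the 64-case training cohort. Factor counts are printed at SIDS vs others granularity; group_sizes additionally split the 23 others into internal/external causes. Nested factors (co_sleeping, sleep_position) are counted over death_during_sleep=yes records only. sids_age_stratified holds the printed age-band joint counts for the SIDS group.",
  "group_sizes": {"SIDS": 41, "internal": 11, "external": 12},
  "factor_counts": {
    "age_band": {"SIDS": {"0-2": 13, "3-6": 24, "7-11": 4}, "others": {"0-2": 9, "3-6": 8, "7-11": 6}},
    "sex": {"SIDS": {"male": 22, "female": 19}, "others": {"male": 14, "female": 9}},
    "gestational_age": {"SIDS": {"<37": 4, ">=37": 37}, "others": {"<37": 1, ">=37": 22}},
    "birth_weight": {"SIDS": {"<2500": 10, ">=2500": 31}, "others": {"<2500": 3, ">=2500": 20}},
    "death_during_sleep": {"SIDS": {"yes": 41, "no": 0}, "others": {"yes": 13, "no": 10}},
    "co_sleeping": {"SIDS": {"yes": 32, "no": 9}, "others": {"yes": 5, "no": 8}},
    "sleep_position": {"SIDS": {"supine": 17, "prone": 19, "other": 2, "unknown": 3}, "others": {"supine": 3, "prone": 4, "other": 3, "unknown": 3}},
    "maternal_age": {"SIDS": {"<=19": 4, "20-34": 24, ">=35": 13}, "others": {"<=19": 1, "20-34": 14, ">=35": 8}},
    "siblings": {"SIDS": {"0": 11, "1": 15, ">=2": 15}, "others": {"0": 8, "1": 10, ">=2": 5}},
    "suid_history": {"SIDS": {"yes": 2, "no": 39}, "others": {"yes": 0, "no": 23}},
    "breastfeeding": {"SIDS": {"yes": 21, "no": 20, "unknown": 0}, "others": {"yes": 11, "no": 10, "unknown": 2}},
    "passive_smoking": {"SIDS": {"yes": 21, "no": 9, "unknown": 11}, "others": {"yes": 9, "no": 3, "unknown": 11}},
    "alcohol_influence": {"SIDS": {"yes": 4, "no": 37}, "others": {"yes": 5, "no": 18}},
    "vaccination": {"SIDS": {"yes": 10, "no": 30, "unknown": 1}, "others": {"yes": 9, "no": 13, "unknown": 1}},
    "maltreatment": {"SIDS": {"yes": 19, "no": 22}, "others": {"yes": 6, "no": 17}},
    "infection_symptoms": {"SIDS": {"yes": 10, "no": 31}, "others": {"yes": 1, "no": 22}}
  },
  "sids_age_stratified": {
    "co_sleeping": {"0-2": {"yes": 12, "no": 1}, "3-6": {"yes": 17, "no": 7}, "7-11": {"yes": 3, "no": 1}},
    "breastfeeding": {"0-2": {"yes": 11, "no": 2}, "3-6": {"yes": 7, "no": 17}, "7-11": {"yes": 3, "no": 1}}
  }
}
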