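{
 "name": "model1",
 "schema_version": 1,
 "outcome": "diagnosis",
 "direction": "causal",
 "nodes": [
  {
   "name": "diagnosis",
   "states": [
    "SIDS",
    "non_SIDS"
   ]
  },
  {
   "name": "age_band",
   "states": [
    "0-2",
    "3-6",
    "7-11"
   ]
  },
  {
   "name": "sex",
   "states": [
    "male",
    "female"
   ]
  },
  {
   "name": "gestational_age",
   "states": [
    "<37",
    ">=37"
   ]
  },
  {
   "name": "birth_weight",
   "states": [
    "<2500",
    ">=2500"
   ]
  },
  {
   "name": "death_during_sleep",
   "states": [
    "yes",
    "no"
   ]
  },
  {
   "name": "co_sleeping",
   "states": [
    "yes",
    "no",
    "NA"
   ]
  },
  {
   "name": "sleep_position",
   "states": [
    "supine",
    "prone",
    "other",
    "unknown",
    "NA"
   ]
  },
  {
   "name": "maternal_age",
   "states": [
    "<=19",
    "20-34",
    ">=35"
   ]
  },
  {
   "name": "siblings",
   "states": [
    "0",
    "1",
    ">=2"
   ]
  },
  {
   "name": "suid_history",
   "states": [
    "yes",
    "no"
   ]
  },
  {
   "name": "breastfeeding",
   "states": [
    "yes",
    "no",
    "unknown"
   ]
  },
  {
   "name": "passive_smoking",
   "states": [
    "yes",
    "no",
    "unknown"
   ]
  },
  {
   "name": "alcohol_influence",
   "states": [
    "yes",
    "no"
   ]
  },
  {
   "name": "vaccination",
   "states": [
    "yes",
    "no",
    "unknown"
   ]
  },
  {
   "name": "maltreatment",
   "states": [
    "yes",
    "no"
   ]
  },
  {
   "name": "infection_symptoms",
   "states": [
    "yes",
    "no"
   ]
  }
 ],
 "edges": [
  [
   "age_band",
   "death_during_sleep"
  ],
  [
   "death_during_sleep",
   "co_sleeping"
  ],
  [
   "age_band",
   "co_sleeping"
  ],
  [
   "death_during_sleep",
   "sleep_position"
  ],
  [
   "death_during_sleep",
   "diagnosis"
  ],
  [
   "co_sleeping",
   "diagnosis"
  ],
  [
   "infection_symptoms",
   "diagnosis"
  ]
 ]
}
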