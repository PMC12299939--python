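[
  {"id": 1, "level": 1, "predicate": "vl_detectable",
   "description": "Detectable viral load (>=50 copies/mL) ever recorded"},
  {"id": 2, "level": 1, "predicate": "qual_positive_with_condition",
   "description": "Positive HIV antigen/antibody test with an HIV condition code"},
  {"id": 3, "level": 1, "predicate": "cd4_low",
   "description": "CD4 count <=200 cells/uL ever recorded"},
  {"id": 4, "level": 1, "predicate": "qual_positive_with_art",
   "description": "Positive HIV antigen/antibody test with HIV treatment exposure"},
  {"id": 5, "level": 1, "predicate": "vl_suppressed_with_art",
   "description": "Suppressed viral load (<50 copies/mL) on HIV treatment"},
  {"id": 6, "level": 1, "predicate": "qual_positive",
   "description": "Positive HIV antigen/antibody test alone"},
  {"id": 7, "level": 2, "predicate": "condition_art_resultless",
   "description": "HIV condition plus HIV treatment plus lab orders without results"},
  {"id": 8, "level": 2, "predicate": "repeat_condition_with_art", "parameters": {"min_dates": 2},
   "description": "HIV condition codes on >=2 distinct dates plus HIV treatment"},
  {"id": 9, "level": 2, "predicate": "repeat_condition", "parameters": {"min_dates": 2},
   "description": "HIV condition codes on >=2 distinct dates"},
  {"id": 10, "level": 3, "predicate": "art_repeat", "parameters": {"min_rows": 2},
   "description": "HIV treatment drug exposure alone, >=2 rows"},
  {"id": 11, "level": 3, "predicate": "hiv_drug_any",
   "description": "Residual HIV drug exposure (single treatment row or unresolved ritonavir)"},
  {"id": 12, "level": 3, "predicate": "single_condition",
   "description": "A single HIV condition date and nothing else"}
]
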