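# Default reportable-outcome code sets for the proposed district
# climate-and-health surveillance system.
#
# Heat outcomes: heat-related deaths (ICD-10 X30) and heat stress
# hospitalizations / emergency department visits (ICD-9 992, E900.0,
# E900.9), restricted to the May-September warm season.
# Flood outcomes: unintentional drowning mortalities (ICD-10 W69, W70,
# X38) and flooding-related hospitalizations / ED visits (ICD-9 E908.2,
# E908.9, E910.8, E910.9), matched year-round.
# Drought: trigger only — the reportable outcome list is in development,
# so the code set ships empty and is configurable.
heat:
  icd10: [X30]
  icd9: ["992", E900.0, E900.9]
  season:
    start: "05-01"
    end: "09-30"
flood:
  icd10: [W69, W70, X38]
  icd9: [E908.2, E908.9, E910.8, E910.9]
drought:
  icd10: []
  icd9: []
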