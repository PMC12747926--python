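# Example analysis configuration. Any omitted key keeps its default.
# Dates are ISO strings; intervals are half-open.

study_start: 2011-01-01
study_end: 2021-01-01
identification_start: 2012-01-01
identification_end: 2020-01-01
followup_cutoff: 2020-12-31

grace_nsaid_days: 14
grace_steroid_days: 14
grace_csdmard_days: 14
grace_biologic_days: 60
chronic_days: 90
nsaid_min_span_days: 15
age_cutoff_years: 16

prevalence_mode: cumulative      # or active_claim
spa_same_day_only: false
event_definition: index_drug     # or any_biologic

# Code lists may be replaced wholesale; structure: group -> code system -> codes.
dx_codes:
  JIA:
    ICD9CM: ["714.30", "714.31", "714.32", "714.33"]
    ICD10CM: ["M08.0", "M08.2", "M08.3", "M08.4", "M08.8", "M08.9"]
  SpA_feature:
    ICD9CM: ["720.0", "720.2", "720.8", "720.9", "696.0"]
    ICD10CM: ["M45", "M46.1", "M46.8", "M46.9", "L40.5"]
  uveitis:
    ICD9CM: ["364.00", "364.3"]
    ICD10CM: ["H20.0", "H20.9"]
  psoriasis:
    ICD9CM: ["696.1"]
    ICD10CM: ["L40.0"]

drug_classes:
  NSAID: [naproxen, ibuprofen, diclofenac, celecoxib, indomethacin]
  steroid: [prednisolone, methylprednisolone]
  csDMARD: [methotrexate, sulfasalazine, hydroxychloroquine, leflunomide]
  biologic: [etanercept, adalimumab, tocilizumab, abatacept]
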