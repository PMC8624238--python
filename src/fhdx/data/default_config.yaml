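# Default pipeline configuration.
#
# DLCN point values follow the published Dutch Lipid Clinic Network table
# (WHO 1999 formulation); bands: possible 3-5, probable 6-8, definite >8.
#
# The 95th-percentile LDL-C table below is SYNTHETIC (plausible mmol/L
# values, NOT population-derived) and must be replaced with real reference
# data before any clinical use.

dlcn_points:
  family:
    premature_cvd: 1
    ldl_above_p95: 1
    xanthoma_or_arcus: 2
    child_ldl_above_p95: 2
  clinical:
    premature_cad: 2
    premature_cerebral_or_peripheral: 1
  physical:
    tendon_xanthomata: 6
    arcus_cornealis_before_45: 4
  ldl_bands:
    - {min_ldl: 8.5, points: 8}
    - {min_ldl: 6.5, points: 5}
    - {min_ldl: 5.0, points: 3}
    - {min_ldl: 4.0, points: 1}
  dna_functional_mutation: 8

dlcn_bands:
  possible: [3, 5]
  probable: [6, 8]
  definite: [9, null]

dlcn_group_aggregation: max
friedewald_max_tg: 4.5
friedewald_direct_ldl_threshold: 4.5

percentile_table:
  - {sex: F, age_min: 0,  age_max: 17, p95_ldl: 3.3}
  - {sex: M, age_min: 0,  age_max: 17, p95_ldl: 3.3}
  - {sex: F, age_min: 18, age_max: 34, p95_ldl: 3.9}
  - {sex: M, age_min: 18, age_max: 34, p95_ldl: 4.0}
  - {sex: F, age_min: 35, age_max: 44, p95_ldl: 4.2}
  - {sex: M, age_min: 35, age_max: 44, p95_ldl: 4.4}
  - {sex: F, age_min: 45, age_max: 54, p95_ldl: 4.5}
  - {sex: M, age_min: 45, age_max: 54, p95_ldl: 4.7}
  - {sex: F, age_min: 55, age_max: 120, p95_ldl: 4.8}
  - {sex: M, age_min: 55, age_max: 120, p95_ldl: 4.8}

filter:
  rare_af_threshold: 0.005
  conservation_percentile_threshold: 0.7
  predictor_damaging_fraction: 0.5
  excluded_assertions: [benign, likely_benign]

acmg:
  ba1_af_threshold: 0.05
  pm2_af_threshold: 0.0001

mlpa:
  deletion_threshold: 0.7
  duplication_threshold: 1.3
  homozygous_deletion_threshold: 0.25
  transcript: NM_000527.4

seed: 0
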