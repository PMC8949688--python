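# Default two-arm cohort simulation: a randomized internet-vs-telephone
# survey with covariate-dependent nonresponse and an additive telephone-arm
# interviewer effect on the latent 0-100 scale scores.
#
# Categorical marginals follow the pooled baseline table of a two-arm
# posthospitalization cohort (1680 discharged patients from 5 wards).
# Response targets are the arms' marginal response probabilities; the
# response-model intercepts are calibrated per arm so the realized cohort
# hits these targets in expectation.  The interviewer-effect vector is a
# realistic preset patterned on observed matched telephone-internet score
# differences; it is a preset, not ground truth.

n_per_arm: 840
missing_item_rate: 0.01
item_jitter_sd: 6.0
scale_correlation: 0.6

covariates:
  sex: {female: 0.4375, male: 0.5625}
  hospitalization_type: {conventional: 0.4274, day: 0.4792, week: 0.0934}
  ward:
    surgery: 0.2440
    gastroenterology: 0.2440
    hepatogastroenterology: 0.1232
    infectious: 0.2441
    internal: 0.1447
  employment:
    employed: 0.6070
    job_seeker: 0.0728
    retired: 0.1640
    student: 0.0650
    health_limited: 0.0710
    without_work: 0.0137
    other: 0.0065
  education:
    primary: 0.0917
    high_school: 0.3014
    superior_short: 0.1543
    graduate: 0.4526
  relationship_status: {alone: 0.4810, couple: 0.5190}
  income:
    lt_450: 0.0447
    "450_1000": 0.0488
    "1000_1500": 0.0869
    "1500_2100": 0.1275
    "2100_2800": 0.1114
    "2800_4200": 0.1543
    ge_4200: 0.1221
    no_response: 0.3043
  insurance:
    state_aid: 0.0357
    compulsory: 0.0756
    complementary: 0.8887

numeric_covariates:
  age: {mean: 47.0, sd: 15.0, min: 18.0, max: 95.0}
  length_of_stay: {meanlog: 0.5, sdlog: 1.2, min: 1.0, max: 60.0}

response_model:
  target_rates: {internet: 0.292, telephone: 0.75}
  coefficients:
    age: 0.010
    "education:graduate": 0.25
    "education:primary": -0.25
    "employment:retired": 0.20
    "employment:student": -0.30
    "employment:health_limited": -0.20
    "relationship_status:couple": 0.15
    "income:no_response": -0.10

latent_model:
  means: {PF: 76.0, RP: 55.0, BP: 66.0, GH: 55.0, VT: 48.0, SF: 70.0, RE: 67.0, MH: 63.0}
  sds: {PF: 20.0, RP: 62.0, BP: 27.0, GH: 18.0, VT: 17.0, SF: 26.0, RE: 58.0, MH: 16.0}
  loadings:
    PF: {age: -0.30, length_of_stay: -0.50, "employment:health_limited": -12.0}
    RP: {age: -0.10, length_of_stay: -0.80, "employment:health_limited": -15.0}
    BP: {age: -0.10, length_of_stay: -0.50, "employment:health_limited": -10.0}
    GH: {age: -0.15, length_of_stay: -0.60, "employment:health_limited": -12.0}
    VT: {age: -0.05, length_of_stay: -0.40, "employment:health_limited": -8.0}
    SF: {length_of_stay: -0.50, "employment:health_limited": -10.0, "relationship_status:couple": 2.0}
    RE: {length_of_stay: -0.40, "employment:health_limited": -10.0}
    MH: {age: 0.05, "relationship_status:couple": 2.0, "employment:health_limited": -8.0}

interviewer_effect:
  PF: 4.57
  RP: 9.39
  BP: 4.56
  GH: 0.04
  VT: 0.82
  SF: 7.96
  RE: 9.93
  MH: 5.01
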