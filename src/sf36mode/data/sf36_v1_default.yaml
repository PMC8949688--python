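# Default SF-36 version 1 (standard 4-week recall) scoring tables.
#
# Item numbering follows the standard v1 ordering 1-36; item 2 is the
# health-transition item, which enters no score.  Recode tables map each
# precoded answer to its calibrated item value (reverse-coded items and the
# two empirically recalibrated items -- general-health rating and pain
# intensity -- included).  Pain-interference (item 22) uses the
# unconditional calibration; see docs/methods.md.
#
# Norm means/SDs and the PCS/MCS factor-score coefficients are the published
# 1990 US general-population values used in standard norm-based component
# scoring.  Substitute country-specific tables by editing a copy of this
# file and passing it to ScoringSpec.from_yaml.

scales:
  PF: [3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
  RP: [13, 14, 15, 16]
  BP: [21, 22]
  GH: [1, 33, 34, 35, 36]
  VT: [23, 27, 29, 31]
  SF: [20, 32]
  RE: [17, 18, 19]
  MH: [24, 25, 26, 28, 30]

excluded_items: [2]

recode_tables:
  1:  {1: 5.0, 2: 4.4, 3: 3.4, 4: 2.0, 5: 1.0}
  2:  {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}
  3:  {1: 1, 2: 2, 3: 3}
  4:  {1: 1, 2: 2, 3: 3}
  5:  {1: 1, 2: 2, 3: 3}
  6:  {1: 1, 2: 2, 3: 3}
  7:  {1: 1, 2: 2, 3: 3}
  8:  {1: 1, 2: 2, 3: 3}
  9:  {1: 1, 2: 2, 3: 3}
  10: {1: 1, 2: 2, 3: 3}
  11: {1: 1, 2: 2, 3: 3}
  12: {1: 1, 2: 2, 3: 3}
  13: {1: 1, 2: 2}
  14: {1: 1, 2: 2}
  15: {1: 1, 2: 2}
  16: {1: 1, 2: 2}
  17: {1: 1, 2: 2}
  18: {1: 1, 2: 2}
  19: {1: 1, 2: 2}
  20: {1: 5, 2: 4, 3: 3, 4: 2, 5: 1}
  21: {1: 6.0, 2: 5.4, 3: 4.2, 4: 3.1, 5: 2.2, 6: 1.0}
  22: {1: 6.0, 2: 4.75, 3: 3.5, 4: 2.25, 5: 1.0}
  23: {1: 6, 2: 5, 3: 4, 4: 3, 5: 2, 6: 1}
  24: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 6}
  25: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 6}
  26: {1: 6, 2: 5, 3: 4, 4: 3, 5: 2, 6: 1}
  27: {1: 6, 2: 5, 3: 4, 4: 3, 5: 2, 6: 1}
  28: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 6}
  29: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 6}
  30: {1: 6, 2: 5, 3: 4, 4: 3, 5: 2, 6: 1}
  31: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 6}
  32: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}
  33: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}
  34: {1: 5, 2: 4, 3: 3, 4: 2, 5: 1}
  35: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}
  36: {1: 5, 2: 4, 3: 3, 4: 2, 5: 1}

scale_ranges:
  PF: [10, 30]
  RP: [4, 8]
  BP: [2, 12]
  GH: [5, 25]
  VT: [4, 24]
  SF: [2, 10]
  RE: [3, 6]
  MH: [5, 30]

norm_means:
  PF: 84.52404
  RP: 81.19907
  BP: 75.49196
  GH: 72.21316
  VT: 61.05453
  SF: 83.59753
  RE: 81.29467
  MH: 74.84212

norm_sds:
  PF: 22.89490
  RP: 33.79729
  BP: 23.55879
  GH: 20.16964
  VT: 20.86942
  SF: 22.37642
  RE: 33.02717
  MH: 18.01189

summary_weights:
  PCS:
    PF: 0.42402
    RP: 0.35119
    BP: 0.31754
    GH: 0.24954
    VT: 0.02877
    SF: -0.00753
    RE: -0.19206
    MH: -0.22069
  MCS:
    PF: -0.22999
    RP: -0.12329
    BP: -0.09731
    GH: -0.01571
    VT: 0.23534
    SF: 0.26876
    RE: 0.43407
    MH: 0.48581
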