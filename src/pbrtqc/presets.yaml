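# Per-analyte monitoring presets for six serum tumor markers.
#
# `range_lo`/`range_hi` are the analyzer's reportable fluctuation range;
# values are clipped to this interval both when generating synthetic
# streams and after bias injection.  `tea` is the total allowable error
# budget used to size injected biases.  `ref_median` is the training-set
# median; it anchors the constant-error formula and the synthetic-stream
# calibration.  `dist_targets` carries the distribution summaries the
# synthetic generator is calibrated against (the `train` entry) together
# with the corresponding held-out summaries (`test`), as
# [mean, median, sd, skewness, kurtosis].
analytes:
  CEA:
    unit: ng/mL
    range_lo: 0.30
    range_hi: 1000.0
    tea: 0.25
    ref_median: 1.92
    dist_targets:
      train: [6.05, 1.92, 46.06, 21.39, 652.01]
      test: [5.57, 1.81, 40.60, 19.20, 421.62]
  AFP:
    unit: ng/mL
    range_lo: 0.91
    range_hi: 1210.0
    tea: 0.25
    ref_median: 2.85
    dist_targets:
      train: [9.34, 2.85, 80.10, 18.15, 490.28]
      test: [8.75, 2.85, 73.73, 15.24, 237.74]
  CA19-9:
    unit: U/mL
    range_lo: 2.00
    range_hi: 1000.0
    tea: 0.25
    ref_median: 11.50
    dist_targets:
      train: [27.48, 11.50, 107.84, 32.52, 2699.22]
      test: [27.15, 10.80, 122.64, 34.95, 2343.66]
  CA125:
    unit: U/mL
    range_lo: 1.00
    range_hi: 5000.0
    tea: 0.25
    ref_median: 11.30
    dist_targets:
      train: [24.53, 11.30, 129.85, 27.40, 917.40]
      test: [21.18, 11.80, 90.69, 32.24, 1459.62]
  CYFRA21-1:
    unit: ng/mL
    range_lo: 0.10
    range_hi: 500.0
    tea: 0.25
    ref_median: 2.17
    dist_targets:
      train: [2.95, 2.17, 6.92, 37.46, 2072.48]
      test: [3.19, 2.15, 13.05, 32.36, 1172.57]
  PROGRP:
    unit: pg/mL
    range_lo: 3.00
    range_hi: 5000.0
    tea: 0.25
    ref_median: 47.60
    dist_targets:
      train: [66.66, 47.60, 203.33, 20.26, 450.96]
      test: [65.52, 46.20, 202.08, 20.54, 469.43]

# Companion analytes: the two markers most frequently co-ordered with
# each target, used as extra coordinates for sample pre-classification.
companions:
  CEA: [AFP, CA19-9]
  AFP: [CEA, CA19-9]
  CA19-9: [AFP, CEA]
  CA125: [CEA, CA19-9]
  CYFRA21-1: [PROGRP, CEA]
  PROGRP: [CYFRA21-1, CEA]
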