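# Default synthetic-cohort configuration: per-group plasma marker moments
# (natural-scale mean and SD, pg/mL; Abeta42/40 unitless), age moments,
# female fraction, group sizes, and amyloid-positive mixture fractions for
# the memory-clinic development cohort the generator emulates.
groups:
  - label: SCD_abeta_neg
    group: SCD
    amyloid: negative
    n: 259
    age_mean: 59.0
    age_sd: 8.0
    female_fraction: 0.417
    markers:
      abeta_ratio: {mean: 0.06, sd: 0.02}
      ptau181: {mean: 1.44, sd: 0.88}
      gfap: {mean: 66.0, sd: 36.0}
      nfl: {mean: 11.4, sd: 6.7}
  - label: SCD_abeta_pos
    group: SCD
    amyloid: positive
    n: 64
    age_mean: 68.0
    age_sd: 6.0
    female_fraction: 0.547
    markers:
      abeta_ratio: {mean: 0.05, sd: 0.01}
      ptau181: {mean: 2.30, sd: 1.01}
      gfap: {mean: 124.0, sd: 66.0}
      nfl: {mean: 17.8, sd: 6.7}
  - label: MCI_abeta_neg
    group: MCI
    amyloid: negative
    n: 116
    age_mean: 63.0
    age_sd: 8.0
    female_fraction: 0.198
    markers:
      abeta_ratio: {mean: 0.06, sd: 0.01}
      ptau181: {mean: 1.53, sd: 0.79}
      gfap: {mean: 73.6, sd: 34.0}
      nfl: {mean: 15.6, sd: 13.0}
  - label: MCI_abeta_pos
    group: MCI
    amyloid: positive
    n: 167
    age_mean: 67.0
    age_sd: 7.0
    female_fraction: 0.431
    markers:
      abeta_ratio: {mean: 0.05, sd: 0.01}
      ptau181: {mean: 2.39, sd: 1.16}
      gfap: {mean: 116.0, sd: 50.0}
      nfl: {mean: 17.7, sd: 9.9}
  - label: AD_dementia
    group: AD_dementia
    n: 320
    age_mean: 64.0
    age_sd: 8.0
    female_fraction: 0.581
    abeta_positive_fraction: 1.0
    markers:
      abeta_ratio: {mean: 0.05, sd: 0.01}
      ptau181: {mean: 2.81, sd: 1.08}
      gfap: {mean: 145.0, sd: 70.0}
      nfl: {mean: 20.3, sd: 12.0}
  - label: FTD
    group: FTD
    n: 162
    age_mean: 63.0
    age_sd: 9.0
    female_fraction: 0.469
    abeta_positive_fraction: 0.17
    markers:
      abeta_ratio: {mean: 0.06, sd: 0.01}
      ptau181: {mean: 1.75, sd: 1.45}
      gfap: {mean: 103.0, sd: 59.0}
      nfl: {mean: 38.3, sd: 38.0}
  - label: DLB
    group: DLB
    n: 111
    age_mean: 69.0
    age_sd: 7.0
    female_fraction: 0.171
    abeta_positive_fraction: 0.49
    markers:
      abeta_ratio: {mean: 0.05, sd: 0.01}
      ptau181: {mean: 2.00, sd: 1.25}
      gfap: {mean: 118.0, sd: 72.0}
      nfl: {mean: 22.8, sd: 21.0}
marker_correlation: 0.3
seed: 0
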