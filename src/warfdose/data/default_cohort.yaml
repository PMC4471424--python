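# Marginal description of the multiethnic warfarin cohort used to parameterize
# the default synthetic-cohort specification and the default schema.
#
# Continuous variables: truncated-normal parameters (mean/sd of the untruncated
# normal, hard min/max bounds). Categorical variables: printed percentage
# frequencies per code (normalized to probabilities at load time; the age rows
# sum to 99.99% from rounding).
continuous:
  target_inr: {mean: 2.5, sd: 0.1, min: 1.8, max: 3.5}
  bsa: {mean: 1.94, sd: 0.3, min: 1.2, max: 3.4}
categorical_percent:
  race: {1: 62.85, 2: 15.48, 3: 21.67}
  age_decade: {1: 0.21, 2: 2.22, 3: 4.46, 4: 10.48, 5: 19.02, 6: 24.14, 7: 26.74, 8: 12.06, 9: 0.66}
  gender: {0: 43.00, 1: 57.00}
  dvt_pe: {0: 90.77, 1: 9.23}
  diabetes: {0: 82.61, 1: 17.39}
  chf: {0: 82.42, 1: 17.58}
  valve_replacement: {0: 76.54, 1: 23.46}
  aspirin: {0: 75.50, 1: 24.50}
  simvastatin: {0: 85.15, 1: 14.85}
  atorvastatin: {0: 89.92, 1: 10.08}
  fluvastatin: {0: 99.60, 1: 0.40}
  lovastatin: {0: 98.02, 1: 1.98}
  pravastatin: {0: 97.26, 1: 2.74}
  rosuvastatin: {0: 99.32, 1: 0.68}
  amiodarone: {0: 94.03, 1: 5.97}
  carbamazepine: {0: 99.01, 1: 0.99}
  phenytoin: {0: 99.06, 1: 0.94}
  rifampin: {0: 99.86, 1: 0.14}
  sulfonamide_abx: {0: 99.46, 1: 0.54}
  macrolide_abx: {0: 99.72, 1: 0.28}
  antifungal_azoles: {0: 99.36, 1: 0.64}
  smoker: {0: 88.10, 1: 11.90}
  enzyme: {0: 97.95, 1: 2.05}
# Fraction of patients in the high-required-dose class (therapeutic dose
# > 30 mg/wk), the calibration target for the synthetic dose mechanism.
hrd_class_percent: 50.18
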