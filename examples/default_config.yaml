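# Reference run configuration: every key at its default value.
# Any subset of keys may be given; unknown keys are rejected.
seed: 0
payoff:
  h: 2100.0
  m: 1300.0
  l: 700.0
  cost_rate: 0.25
  intermediate_fraction: 0.5
cohort:
  n_participants: 33
  rounds_per_session: 18
  n_lottery: 6
  dictator_fraction: 0.3333333333333333
  policy_mixture:
  - weight: 0.85
    w_self: 1.0
    w_total: 0.0
    w_fair: 0.0
    risk: expected_value
    temperature: 100.0
    tremble: 0.1
  - weight: 0.08
    w_self: 1.0
    w_total: 0.0
    w_fair: 0.25
    risk: expected_value
    temperature: 100.0
    tremble: 0.1
  - weight: 0.07
    w_self: 1.0
    w_total: 0.0
    w_fair: 0.0
    risk: maximin
    temperature: 80.0
    tremble: 0.1
affect:
  baseline_mean: 46.0
  baseline_sd: 12.0
  play_effect_accordance: 10.4
  play_effect_non_accordance: -13.3
  disclosure_effect_accordance: -15.6
  disclosure_effect_non_accordance: 19.6
  p_zero_change: 0.3076923076923077
  income_slope: -150.0
  income_slope_center: 0.5
  noise_sd: 6.0
  min_disclosure_magnitude: 1.0
  p_accordance: 0.38
  attitude_correlation: 0.8
neural:
  mu: 0.0
  equality_effect: 0.3
  voi_effect: -0.2
  interaction_effect: 0.5
  attitude_effect: 0.4
  income_slope: -0.5
  random_effect_sd: 0.3
  noise_sd: 1.0
analysis:
  bootstrap_b: 2000
  alpha: 0.05
  equal_var: false
  chi2_correction: false
  per_participant_cells: false
  relative_income_denominator: sum
  target:
    condition: voi
    rule: equality
  baseline:
    condition: high
    rule: inequality
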