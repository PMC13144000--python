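# Reference calibration for Australia: high-UV population with publicly
# financed melanoma treatment. Economic parameters are the published
# Australian figures (AIHW lifetime risk, trial-based relative risk,
# retail sunscreen price); cohort block drives the aggregate burden
# estimate, with the externally reported headline total for cross-checking.
economic:
  p: 0.0674          # AIHW lifetime melanoma risk
  rr: 0.5            # relative risk under daily sunscreen use
  k_med: 11788       # direct medical cost per case, AUD
  v_per_qaly: 75000  # monetary value per QALY, AUD
  dqaly: 1.0         # QALY loss per case
  price: 10.99       # AUD per bottle
  volume_ml: 110
  ml_per_day: 20
  days_per_year: 90
  years: 60
  theta: 0.20        # private share of the per-case loss
risks: [0.0674, 0.20, 0.25, 0.30]
cohort:
  population: 27600000
  share_age: 0.23        # aged 60+
  share_sex: 0.496       # male among 60+
  share_risk: 0.60       # elevated melanoma risk (fair skin / European ancestry)
  cost_per_case: 8679
  headline_total_aud: 18367558099   # reported reference total, cross-checked in the report
conversion_rate: 0.71    # USD per AUD
dynamics:
  x0: 0.5
  horizon: 10.0
  n_points: 201
policy:
  subsidy: 0.0
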