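{
  "comment": "Synthetic study-replica scenario: 3 operators, 131 cases, 222 sampled nodes, with a four-phase institutional failure-rate profile (learning / proficient / worsening / proficient) aligned in fractional study time across operators. Covariate prevalences and effects are illustrative, not calibrated.",
  "seed": 2008,
  "nodes_per_case": {"1": 0.5, "2": 0.35, "3": 0.15},
  "operators": [
    {"operator_id": "A", "n_cases": 47, "phases": [[18, 0.42], [26, 0.04], [12, 0.5], [28, 0.04]]},
    {"operator_id": "B", "n_cases": 50, "phases": [[20, 0.42], [26, 0.04], [13, 0.5], [30, 0.04]]},
    {"operator_id": "C", "n_cases": 34, "phases": [[11, 0.42], [14, 0.04], [7, 0.5], [17, 0.04]]}
  ],
  "covariates": {
    "attending_assist": {"prevalence": 0.35, "log_odds": -1.5},
    "cytopathologist": {"prevalence": 0.5, "log_odds": -0.3},
    "high_midazolam": {"prevalence": 0.29, "log_odds": 0.2},
    "high_fentanyl": {"prevalence": 0.17, "log_odds": 0.3}
  }
}
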