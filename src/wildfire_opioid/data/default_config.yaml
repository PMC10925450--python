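# Default run configuration — reproduces the published parameter table.
baseline_misuse_prev: 0.053      # past-year opioid misuse, U.S. ages 18-25
baseline_anxiety_prev: 0.066     # past-year anxiety, U.S. young adults
or_misuse_given_anxiety:         # OR for misuse given fire-related anxiety
  family: lognormal
  a: 3.04                        # natural-scale mean
  b: 1.07                        # natural-scale sd
  dialect: natural_moments
anxiety_prev_post_fire:          # anxiety prevalence among the wildfire-exposed
  family: beta
  a: 10.5
  b: 70.0
rr_incident_fire_anxiety: 5.0    # hypothetical RR, incident-anxiety stratum (S2/S3)
rr_worsened_preexisting: 5.0     # hypothetical RR, worsened pre-existing stratum (S3)
or_as_rr: false                  # calibrate the drawn OR as a true odds ratio
n_iterations: 50000
seed: 1
output_directory: results
export_draws: true
density_bins: 100
scenarios: [S1, S2, S3]
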