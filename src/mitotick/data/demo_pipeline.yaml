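# Demo pipeline configuration: a reduced synthetic cohort that runs the
# full analysis (simulate -> clock -> deconvolve -> associate -> progress
# -> correlations) in a few seconds.
seed: 1
simulate:
  n_cpgs_total: 2000
  n_clock_cpgs: 200
  n_reference_cpgs_per_type: 30
  n_age_cpgs: 30
  n_cases: 200
  n_controls: 200
  n_control_probes: 200
  n_progression_patients: 100
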