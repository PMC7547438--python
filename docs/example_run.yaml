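# Small end-to-end pipeline run (about a minute on one core).
# The simulation block accepts every SimulationConfig field; omitted model
# options keep their defaults (random intercept + demand slope, 9 nodes).
mode: simulate
outdir: hipwait_run
covariates: [age_group, sex, prefracture_status, medical_reason_for_delay]
random_effects: intercept
nodes: 7
subgroups: false
simulation:
  n_hospitals: 8
  start: "2004-01-01"
  end: "2005-12-31"
  arrival_rate_per_hospital_day: 0.52
  seed: 7
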