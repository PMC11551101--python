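# Full-pipeline demo configuration: synthetic trial at the published
# allocation sizes, ITT + per-protocol outcome analysis, base-case
# economics, and a reduced-budget CEA fit (increase burn_in/kept for
# production-quality posteriors).
simulation:
  n_intervention: 173
  n_control: 167
  seed: 2021

outcomes:
  populations: [ITT_LOCF, per_protocol]
  outcomes: [mcs, eq5d]
  m: 5
  seed: 1

econ:
  intervention_cost_per_year: 15.0
  attribution: full

cea:
  burn_in: 2000
  kept: 2000
  chains: 2
  seed: 7

design:
  sd: 10.0
  rho: 0.7
  delta: 3.0
  alpha: 0.05
  power: 0.80
  dropout_allowance: 0.30
  simulate_replicates: 5000
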