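# Full-scale design configuration with every supported key and its default.
# Any key may be omitted; omitted keys take the values shown here.

design:
  n_subgroups: 5
  n_arms: 2                    # fixed: MM (reference) vs EVT
  # Expected population mix over the five subgroups, in order:
  # Large Core Only; Mild Deficit Only; Distal Occlusion Only;
  # Distal Occlusion + Large core; Distal Occlusion + Mild Deficit.
  # A uniform placeholder: adjust to the registry's observed mix.
  subgroup_proportions: [0.2, 0.2, 0.2, 0.2, 0.2]
  total_enrollment: 10000
  interim_milestones: [2500, 5000, 7500, 10000]   # last = final analysis
  accrual_rate: 52.0           # expected participants per week (Poisson mean)

model:
  model_kind: hierarchical     # independent | hierarchical | hierarchical_drift
  m: 30.0                      # borrowing strength (prior pseudo-sample size)

allocation:
  scheme: rarcomp              # fixed | rar | rarcomp
  gamma: 0.995                 # superiority threshold (calibrate per design!)
  equiv_band: [0.8, 1.2]       # MM:EVT odds-ratio equivalence band
  equiv_threshold: 0.7         # posterior mass required inside the band
  pseudo_n0: 10                # pseudo observations per cell priming allocation
  pseudo_rates:                # prior favorable-outcome rates [MM, EVT]
    - [0.10, 0.25]             # Large Core Only
    - [0.70, 0.84]             # Mild Deficit Only
    - [0.35, 0.55]             # Distal Occlusion Only
    - [0.25, 0.45]             # Distal Occlusion + Large core
    - [0.75, 0.85]             # Distal Occlusion + Mild Deficit

mcmc:
  n_iter: 6000                 # iterations per chain, including burn-in
  n_burn: 1000
  n_chains: 2
  thin: 1

seeds:
  seed: 0
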