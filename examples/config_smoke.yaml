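# Reduced-permutation smoke profile for `skelstats run-all --config ...`:
# a small skeleton and 200 permutations keep a full pipeline pass quick.
# The study-scale setting is n_perm: 5000 on a full-resolution skeleton.
seed: 5
n_perm: 200
alpha: 0.05
age_split: 60
skeleton_shape: [8, 8, 8]
cohort:
  n_subjects: 100
  seed: 5
  mediation: {a: -0.5, b: 0.5, frac_age_effect: 0.1, frac_mediating: 0.5}
exclusions:
  artifacts: 4
  missing_dti: 2
tfce: {h: 2.0, e: 1.0, steps: 100, connectivity: 26}
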