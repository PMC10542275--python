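# False-positive rates of the SFS tests when neutral data from expansion
# histories are scored against a standard-neutral (constant N = 5,000) null.
label: expansion-fpr
demography:
  label: expansion-t0.1
  reference_N: 5000
  time_unit: scaled_N
  epochs:
    - {t_start: 0, size: 47700}
    - {t_start: 0.1, size: 4770}
null_demography:
  label: constant-5000
  reference_N: 5000
  time_unit: generations
  epochs:
    - {t_start: 0, size: 5000}
scenarios: []   # FPR runs use neutral data; see `sweeppower power --help`
stats: [D, H]
region_sfs: {L: 10000, mu: 1.0e-8, r: 1.0e-8, n: 120, focal_pos: 5000}
alpha: 0.05
n_reps: 200
n_null: 1000
seed: 1
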