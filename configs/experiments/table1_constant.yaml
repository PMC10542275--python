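# Constant-population columns of the four-test power table:
# N = 10,000 diploids, printed per-allele selection coefficient 0.005
# (genotype fitnesses 1 : 1.005 : 1.01, i.e. s = 0.01 with h = 0.5 in the
# general 1 : 1+hs : 1+s parameterization), selection starting 2,000
# generations before present (the running text's value; the table caption
# says 2,100), SDN vs SSV with onset frequency 0.1, 120 chromosomes,
# 200 replicates, 1-sided 5% level against a matched constant-model null.
label: table1-constant
demography:
  label: constant-10000
  reference_N: 10000
  time_unit: generations
  epochs:
    - {t_start: 0, size: 10000}
scenarios:
  - {mode: sdn, s: 0.01, h: 0.5, t_age: 2000}
  - {mode: ssv, s: 0.01, h: 0.5, p1: 0.1, t_sel: 2000}
stats: [D, H, rEHH, iHS]
region_sfs: {L: 10000, mu: 1.0e-8, r: 1.0e-8, n: 120, focal_pos: 5000}
region_hap: {L: 500000, mu: 1.0e-8, r: 1.0e-8, n: 120, focal_pos: 0}
alpha: 0.05
n_reps: 200
n_null: 1000
n_null_per_bin: 200
bin_width: 0.05
ehh_distance: 25000
truncation: 0.05
seed: 1
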