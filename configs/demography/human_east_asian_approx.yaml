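# APPROXIMATE, illustrative East-Asian-like piecewise history (synthetic
# stand-in): out-of-Africa bottleneck followed by the Europe-Asia split
# bottleneck ~2,000 generations ago and recovery/growth.  The published
# human model parameterizations live in supplementary material we do not
# reproduce; edit freely.
label: east-asian-approx
reference_N: 10000
time_unit: generations
epochs:
  - {t_start: 0, size: 12000}
  - {t_start: 1000, size: 3000}
  - {t_start: 2000, size: 550}
  - {t_start: 2500, size: 7000}
  - {t_start: 3500, size: 1500}
  - {t_start: 4000, size: 10000}
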