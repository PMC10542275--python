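# 500-generation bottleneck ending tb*N generations ago; Ne = 5,000.
label: bottleneck-tb0.2
reference_N: 5000
time_unit: generations
epochs:
- t_start: 0
  size: 8360
- t_start: 1000.0
  size: 418
- t_start: 1500.0
  size: 8360
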