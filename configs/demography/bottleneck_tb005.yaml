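# 500-generation bottleneck ending tb*N generations ago; Ne = 5,000.
label: bottleneck-tb0.05
reference_N: 5000
time_unit: generations
epochs:
- t_start: 0
  size: 8540
- t_start: 250.0
  size: 427
- t_start: 750.0
  size: 8540
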