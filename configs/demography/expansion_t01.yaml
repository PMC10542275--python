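# Instantaneous 10x expansion; sizes chosen so Ne = 5,000.
label: expansion-t0.1
reference_N: 5000
time_unit: scaled_N
epochs:
- t_start: 0
  size: 47700
- t_start: 0.1
  size: 4770
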