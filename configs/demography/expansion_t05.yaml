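# Instantaneous 10x expansion; sizes chosen so Ne = 5,000.
label: expansion-t0.5
reference_N: 5000
time_unit: scaled_N
epochs:
- t_start: 0
  size: 38900
- t_start: 0.5
  size: 3890
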