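# Constant population, the common effective size of all basic models.
label: constant-5000
reference_N: 5000
time_unit: generations
epochs:
  - {t_start: 0, size: 5000}
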