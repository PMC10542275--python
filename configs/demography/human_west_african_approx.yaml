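# APPROXIMATE, illustrative West-African-like history (synthetic stand-in):
# ancient expansion, no out-of-Africa bottleneck.  Edit freely.
label: west-african-approx
reference_N: 10000
time_unit: generations
epochs:
  - {t_start: 0, size: 16000}
  - {t_start: 5000, size: 10000}
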