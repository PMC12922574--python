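name: invivo_16b_6te
metadata: >
  In-vivo-style abdominal protocol at 3 T: 16 b-values with per-b averages,
  six echo times 47-72 ms in 5 ms steps, respiratory-triggered TR ~1900 ms
  replaced here by the long-TR simulation value.
b_values: [0, 10, 20, 30, 50, 70, 100, 150, 200, 250, 300, 350, 450, 550, 650, 750]
averages: [3, 3, 3, 3, 3, 4, 4, 4, 4, 4, 4, 4, 5, 5, 5, 5]
te_values: [47, 52, 57, 62, 67, 72]
tr_values: [4000]
reference_te: 47
reference_tr: 4000
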