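name: kidney_set2
metadata: >
  Short six-b-value kidney set with the 47-72 ms echo-time ladder.
b_values: [0, 10, 100, 200, 500, 800]
te_values: [47, 52, 57, 62, 67, 72]
tr_values: [4000]
reference_te: 47
reference_tr: 4000
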