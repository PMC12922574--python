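name: liver_consensus
metadata: >
  Community-consensus six-b-value liver IVIM set (CRLB-derived) with the
  extended candidate echo-time ladder 50-100 ms used for protocol design.
b_values: [0, 10, 20, 100, 200, 550]
te_values: [50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100]
tr_values: [4000]
reference_te: 50
reference_tr: 4000
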