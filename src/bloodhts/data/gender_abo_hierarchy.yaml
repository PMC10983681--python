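# Gender x ABO blood-group donation hierarchy (11 nodes, 3 levels).
children:
  Total: [M, F]
  M: [A_M, B_M, AB_M, O_M]
  F: [A_F, B_F, AB_F, O_F]
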