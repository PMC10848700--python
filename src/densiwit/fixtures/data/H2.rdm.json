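{
 "matrix": [
  [
   1.9745399694305081,
   1.6192501080400774e-16
  ],
  [
   1.6192501080400774e-16,
   0.025460030569491286
  ]
 ],
 "mo_space_size": 2,
 "frozen_indices": [],
 "active_indices": [
  0,
  1
 ],
 "n_active_electrons": 2,
 "provenance": "H2/sto-3g (2,2) active-space exact diagonalization",
 "space": "active"
}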