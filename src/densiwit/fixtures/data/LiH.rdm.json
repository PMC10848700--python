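{
 "matrix": [
  [
   1.9967089848422857,
   -0.01997277989745947,
   -4.241035310011721e-17
  ],
  [
   -0.01997277989745947,
   0.00089498351720068,
   3.003366798078031e-19
  ],
  [
   -4.241035310011721e-17,
   3.003366798078031e-19,
   0.002396031640512522
  ]
 ],
 "mo_space_size": 6,
 "frozen_indices": [
  0
 ],
 "active_indices": [
  1,
  2,
  3
 ],
 "n_active_electrons": 2,
 "provenance": "LiH/sto-3g (2,3) active-space exact diagonalization",
 "space": "active"
}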