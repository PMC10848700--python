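{
 "matrix": [
  [
   1.8323177013853078,
   2.9160712893690125e-15,
   1.1404481494864483e-16,
   7.854497082827727e-16
  ],
  [
   2.9160712893690125e-15,
   0.043016931551476546,
   1.0902957219531205e-17,
   1.3076929733114502e-17
  ],
  [
   1.1404481494864483e-16,
   1.0902957219531205e-17,
   0.062332683531607265,
   2.301247697795722e-17
  ],
  [
   7.854497082827727e-16,
   1.3076929733114502e-17,
   2.301247697795722e-17,
   0.06233268353160713
  ]
 ],
 "mo_space_size": 10,
 "frozen_indices": [
  0,
  1
 ],
 "active_indices": [
  2,
  3,
  4,
  5
 ],
 "n_active_electrons": 2,
 "provenance": "Li2/sto-3g (2,4) active-space exact diagonalization",
 "space": "active"
}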