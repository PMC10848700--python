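{
 "matrix": [
  [
   1.9440491122611707,
   4.8675171830441996e-17,
   0.0005777783495974885,
   -0.005190588975242961
  ],
  [
   4.829273645475668e-17,
   1.9440491122611712,
   -0.005190588975235855,
   -0.0005777783495917855
  ],
  [
   0.0005777783495974887,
   -0.005190588975235853,
   0.05595088773882951,
   -1.149444885247767e-16
  ],
  [
   -0.0051905889752429605,
   -0.0005777783495917852,
   -1.154188269752391e-16,
   0.055950887738830064
  ]
 ],
 "mo_space_size": 20,
 "frozen_indices": [
  0,
  1,
  2,
  3,
  4
 ],
 "active_indices": [
  5,
  6,
  7,
  8
 ],
 "n_active_electrons": 4,
 "provenance": "HCN/6-31g (4,4) active-space exact diagonalization",
 "space": "active"
}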