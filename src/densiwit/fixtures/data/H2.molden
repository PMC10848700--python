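[Molden Format]
[Title]
 H2/sto-3g RHF orbitals
[Atoms] AU
H     1    1       0.000000000000       0.000000000000      -0.700521474389
H     2    1       0.000000000000       0.000000000000       0.700521474389
[GTO]
1 0
 s 3 1.00
      3.4252509140E+00     1.5432896730E-01
      6.2391372980E-01     5.3532814230E-01
      1.6885540400E-01     4.4463454220E-01

2 0
 s 3 1.00
      3.4252509140E+00     1.5432896730E-01
      6.2391372980E-01     5.3532814230E-01
      1.6885540400E-01     4.4463454220E-01

[5D]
[7F]
[MO]
 Sym= A
 Ene= -0.5779748065
 Spin= Alpha
 Occup= 2.0000000000
    1  -5.489937772430E-01
    2  -5.489937772430E-01
 Sym= A
 Ene= 0.6696986617
 Spin= Alpha
 Occup= 0.0000000000
    1  -1.210822572378E+00
    2   1.210822572378E+00
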