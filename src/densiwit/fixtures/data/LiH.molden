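[Molden Format]
[Title]
 LiH/sto-3g RHF orbitals
[Atoms] AU
Li    1    3       0.000000000000       0.000000000000       0.000000000000
H     2    1       0.000000000000       0.000000000000       3.013924196125
[GTO]
1 0
 s 3 1.00
      1.6119574750E+01     1.5432896730E-01
      2.9362006630E+00     5.3532814230E-01
      7.9465048700E-01     4.4463454220E-01
 s 3 1.00
      6.3628974690E-01    -9.9967229190E-02
      1.4786005330E-01     3.9951282610E-01
      4.8088678400E-02     7.0011546890E-01
 p 3 1.00
      6.3628974690E-01     1.5591627500E-01
      1.4786005330E-01     6.0768371860E-01
      4.8088678400E-02     3.9195739310E-01

2 0
 s 3 1.00
      3.4252509140E+00     1.5432896730E-01
      6.2391372980E-01     5.3532814230E-01
      1.6885540400E-01     4.4463454220E-01

[5D]
[7F]
[MO]
 Sym= A
 Ene= -2.3486442293
 Spin= Alpha
 Occup= 2.0000000000
    1  -9.912453973569E-01
    2  -3.267808958491E-02
    3   3.551449861362E-19
    4   4.902946739669E-19
    5   6.347088460113E-03
    6  -4.470292000370E-03
 Sym= A
 Ene= -0.2857047648
 Spin= Alpha
 Occup= 2.0000000000
    1  -1.674234697300E-01
    2   4.547932312056E-01
    3  -6.381767746208E-18
    4   1.612354850073E-17
    5   3.461999625364E-01
    6   5.487805482970E-01
 Sym= A
 Ene= 0.0782617856
 Spin= Alpha
 Occup= 0.0000000000
    1   2.099774471087E-01
    2  -7.996171455335E-01
    3  -1.028447727490E-16
    4   2.968482956568E-17
    5   6.121382742465E-01
    6   1.397933274640E-01
 Sym= A
 Ene= 0.1639383542
 Spin= Alpha
 Occup= 0.0000000000
    1  -6.767109490760E-18
    2   3.974357353011E-17
    3   1.246942709409E-01
    4   9.921952120397E-01
    5  -7.197408870099E-18
    6  -4.473607404086E-17
 Sym= A
 Ene= 0.1639383542
 Spin= Alpha
 Occup= 0.0000000000
    1   2.389038058914E-17
    2  -1.023928796907E-16
    3   9.921952120397E-01
    4  -1.246942709409E-01
    5  -3.198395513067E-17
    6   5.039087589304E-17
 Sym= A
 Ene= 0.5491291749
 Spin= Alpha
 Occup= 0.0000000000
    1   9.283822067531E-02
    2  -7.047248276407E-01
    3   1.694382053753E-18
    4   1.375012568771E-17
    5  -9.810007990483E-01
    6   1.187374380334E+00
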