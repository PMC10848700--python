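[Molden Format]
[Title]
 Li2/sto-3g RHF orbitals
[Atoms] AU
Li    1    3       0.000000000000       0.000000000000      -2.525618965528
Li    2    3       0.000000000000       0.000000000000       2.525618965528
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

[5D]
[7F]
[MO]
 Sym= A
 Ene= -2.3300994374
 Spin= Alpha
 Occup= 2.0000000000
    1  -7.004069625487E-01
    2  -3.744942519693E-02
    3   3.009234621630E-17
    4  -1.748356830660E-16
    5  -8.198364952812E-03
    6   7.004069626078E-01
    7   3.744942519863E-02
    8   9.178894934661E-19
    9  -1.679422070170E-18
   10  -8.198364952680E-03
 Sym= A
 Ene= -2.3300792203
 Spin= Alpha
 Occup= 2.0000000000
    1  -7.009138189830E-01
    2  -2.025230214775E-02
    3  -3.785255373038E-17
    4   1.986042340949E-16
    5   1.559332329530E-03
    6  -7.009138189239E-01
    7  -2.025230214460E-02
    8  -5.216305208186E-19
    9   1.692019720807E-18
   10  -1.559332330221E-03
 Sym= A
 Ene= -0.1494395522
 Spin= Alpha
 Occup= 2.0000000000
    1   1.980307052408E-01
    2  -5.672074630349E-01
    3  -1.282646055227E-17
    4   1.316954844682E-16
    5  -1.016255171238E-01
    6   1.980307052408E-01
    7  -5.672074630349E-01
    8   3.776751088650E-18
    9   1.234948948756E-17
   10   1.016255171238E-01
 Sym= A
 Ene= 0.0827909187
 Spin= Alpha
 Occup= 0.0000000000
    1  -1.792495734869E-01
    2   7.008462640167E-01
    3  -3.714991658243E-16
    4   1.329483370288E-15
    5  -3.062383758971E-01
    6   1.792495734869E-01
    7  -7.008462640167E-01
    8  -2.258571682959E-16
    9   6.350917828363E-16
   10  -3.062383758971E-01
 Sym= A
 Ene= 0.1337160195
 Spin= Alpha
 Occup= 0.0000000000
    1   2.711501440644E-17
    2  -6.494811408070E-17
    3  -6.102329264480E-01
    4  -1.339422829638E-01
    5  -1.509955201917E-16
    6   1.390888850621E-18
    7   9.420286786957E-17
    8  -6.102329264480E-01
    9  -1.339422829638E-01
   10   1.606271941681E-16
 Sym= A
 Ene= 0.1337160195
 Spin= Alpha
 Occup= 0.0000000000
    1   6.127484578791E-16
    2  -3.897107389012E-15
    3  -1.339422829638E-01
    4   6.102329264480E-01
    5   6.359028350249E-15
    6  -7.503858275494E-18
    7  -1.457445135500E-15
    8  -1.339422829638E-01
    9   6.102329264480E-01
   10  -5.551459507367E-15
 Sym= A
 Ene= 0.1576473885
 Spin= Alpha
 Occup= 0.0000000000
    1   3.442586512572E-02
    2  -2.908595440085E-01
    3   8.619370984902E-16
    4  -4.251823212152E-15
    5   6.419004214661E-01
    6   3.442586512572E-02
    7  -2.908595440085E-01
    8   1.467687429448E-15
    9  -7.631967672760E-15
   10  -6.419004214661E-01
 Sym= A
 Ene= 0.2404882516
 Spin= Alpha
 Occup= 0.0000000000
    1  -1.202083847023E-17
    2   1.813404435543E-16
    3   6.886146526640E-01
    4   4.703246139952E-01
    5  -5.581055084226E-16
    6  -9.827936710283E-17
    7   4.522607249252E-16
    8  -6.886146526640E-01
    9  -4.703246139952E-01
   10   6.590368771625E-16
 Sym= A
 Ene= 0.2404882516
 Spin= Alpha
 Occup= 0.0000000000
    1   1.864270471227E-19
    2  -3.104302649567E-16
    3   4.703246139952E-01
    4  -6.886146526640E-01
    5   1.344845912384E-15
    6   2.775323101232E-16
    7  -1.016065437683E-15
    8  -4.703246139952E-01
    9   6.886146526640E-01
   10  -1.486026834452E-15
 Sym= A
 Ene= 0.4685429905
 Spin= Alpha
 Occup= 0.0000000000
    1  -1.368908327276E-01
    2   1.233351362965E+00
    3  -1.104178382915E-16
    4  -5.695296883742E-17
    5   1.204605829764E+00
    6   1.368908327276E-01
    7  -1.233351362965E+00
    8   1.185279831673E-17
    9   1.486906329742E-17
   10   1.204605829764E+00
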