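! def2-SV(P): split-valence basis of Weigend and Ahlrichs with polarization
! on non-hydrogen atoms.  Elements H, C, N, O (segmented contractions).
****
H     0
S   3   1.00
     13.0107010          0.19682158E-01
      1.9622572          0.13796524
      0.44453796         0.47831935
S   1   1.00
      0.12194962         1.0000000
****
C     0
S   5   1.00
   1238.4016938          0.54568832082E-02
    186.29004992         0.40638409211E-01
     42.251176346        0.18025593888
     11.676557932        0.46315121755
      4.2914924434       0.44087173314
S   1   1.00
      0.57696339419      1.0000000
S   1   1.00
      0.22365202455      1.0000000
P   3   1.00
      9.4680970621       0.38387871728E-01
      2.0103545142       0.21117025112
      0.54771004707      0.51328172114
P   1   1.00
      0.15268613795      1.0000000
D   1   1.00
      0.80000000         1.0000000
****
N     0
S   5   1.00
   1712.8415853         -0.53934125305E-02
    257.64812677        -0.40221581118E-01
     58.458245853       -0.17931144990
     16.198367905       -0.46376317823
      5.0052600809      -0.44171422662
S   1   1.00
      0.58731856571      1.0000000
S   1   1.00
      0.18764592253      1.0000000
P   3   1.00
     13.571470233       -0.40072398852E-01
      2.9257372874      -0.21807045028
      0.79927750754     -0.51294466049
P   1   1.00
      0.21954348034      1.0000000
D   1   1.00
      1.0000000          1.0000000
****
O     0
S   5   1.00
   2266.1767785         -0.53431809926E-02
    340.87010191        -0.39890039230E-01
     77.363135167       -0.17853911985
     21.479644940       -0.46427684959
      6.6589433124      -0.44309745172
S   1   1.00
      0.80975975668      1.0000000
S   1   1.00
      0.25530772234      1.0000000
P   3   1.00
     17.721504317        0.43394573193E-01
      3.8635505440       0.23094120765
      1.0480920883       0.51375311064
P   1   1.00
      0.27641544411      1.0000000
D   1   1.00
      1.2000000          1.0000000
****
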