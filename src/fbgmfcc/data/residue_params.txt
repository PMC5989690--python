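# Per-atom non-bonded parameters for the shipped residue templates.
# Fixed-charge 12-6 model (Amber-ff14SB-style values); Lorentz-Berthelot
# combining on (rmin/2), geometric on epsilon.
# columns: residue  atom  element  mass(amu)  charge(e)  eps(kcal/mol)  rmin2(A)
ACE  CH3   C  12.011  -0.3662  0.1094  1.9080
ACE  HH31  H   1.008   0.1123  0.0157  1.4870
ACE  HH32  H   1.008   0.1123  0.0157  1.4870
ACE  HH33  H   1.008   0.1123  0.0157  1.4870
ACE  C     C  12.011   0.5972  0.0860  1.9080
ACE  O     O  15.999  -0.5679  0.2100  1.6612
ALA  N     N  14.007  -0.4157  0.1700  1.8240
ALA  H     H   1.008   0.2719  0.0157  0.6000
ALA  CA    C  12.011   0.0337  0.1094  1.9080
ALA  HA    H   1.008   0.0823  0.0157  1.3870
ALA  CB    C  12.011  -0.1825  0.1094  1.9080
ALA  HB1   H   1.008   0.0603  0.0157  1.4870
ALA  HB2   H   1.008   0.0603  0.0157  1.4870
ALA  HB3   H   1.008   0.0603  0.0157  1.4870
ALA  C     C  12.011   0.5973  0.0860  1.9080
ALA  O     O  15.999  -0.5679  0.2100  1.6612
GLY  N     N  14.007  -0.4157  0.1700  1.8240
GLY  H     H   1.008   0.2719  0.0157  0.6000
GLY  CA    C  12.011  -0.0252  0.1094  1.9080
GLY  HA2   H   1.008   0.0698  0.0157  1.3870
GLY  HA3   H   1.008   0.0698  0.0157  1.3870
GLY  C     C  12.011   0.5973  0.0860  1.9080
GLY  O     O  15.999  -0.5679  0.2100  1.6612
NME  N     N  14.007  -0.4157  0.1700  1.8240
NME  H     H   1.008   0.2719  0.0157  0.6000
NME  CH3   C  12.011  -0.1490  0.1094  1.9080
NME  HH31  H   1.008   0.0976  0.0157  1.4870
NME  HH32  H   1.008   0.0976  0.0157  1.4870
NME  HH33  H   1.008   0.0976  0.0157  1.4870
# TIP3P water
HOH  O     O  15.999  -0.8340  0.1520  1.7683
HOH  H1    H   1.008   0.4170  0.0000  0.0000
HOH  H2    H   1.008   0.4170  0.0000  0.0000
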