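# Mock-community recipes: per-strain amplicon DNA mass in ng (500 ng total).
# Strain ids: RE1 = N. frontalis RE1, SR2 = Orpinomyces sp. SR2,
# CaDo16a = Piromyces sp. CaDo16a, CaDo13a = Caecomyces sp. CaDo13a,
# 28xy = Anaeromyces sp. 28xy.
Mock_1:
  RE1: 250
  28xy: 250
Mock_2:
  RE1: 100
  SR2: 100
  CaDo16a: 100
  CaDo13a: 100
  28xy: 100
Mock_3:
  RE1: 250
  SR2: 100
  CaDo16a: 75
  CaDo13a: 50
  28xy: 25
Mock_4:
  RE1: 88.89
  CaDo13a: 10
  CaDo16a: 1
  SR2: 0.1
  28xy: 0.01
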