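description: >
  Left-ventricle Holzapfel-type parameter set printed with the constitutive
  model (age/gender-matched human data).  kappa is effectively zero, i.e. no
  fiber dispersion.  Used in material-level verification, not as a leaflet
  default.
rho: 1.1
C01: 10.678
C10: 0.034
k1: 3.903
k2: 26.900
kappa: 2.427e-8
theta_deg: 29.479
D: 5.0e-4
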