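description: >
  Posterior mitral leaflet Holzapfel-type parameters.  Artifact default, NOT
  patient-derived (see leaflet_anterior.yaml); softer matrix and wider fiber
  angle than the anterior leaflet.
rho: 1.1
C10: 0.70
C01: 9.0
k1: 10.0
k2: 30.0
kappa: 0.08
theta_deg: 40.0
D: 5.0e-4
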