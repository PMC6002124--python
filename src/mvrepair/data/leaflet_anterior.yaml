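description: >
  Anterior mitral leaflet Holzapfel-type parameters.  Artifact default, NOT
  patient-derived: the source study's leaflet constants were never published.
  Chosen so the anterior leaflet is stiffer than the posterior and systolic
  membrane strains stay in a physiological 0.1-0.4 range at 114 mmHg.
rho: 1.1
C10: 1.00
C01: 8.0
k1: 15.0
k2: 25.0
kappa: 0.08
theta_deg: 30.0
D: 5.0e-4
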