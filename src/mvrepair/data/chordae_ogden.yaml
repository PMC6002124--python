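description: >
  Two-term Ogden set for chordae tendineae.  Artifact default, NOT
  patient-derived: small-strain modulus ~17 MPa with strong
  stiffening beyond 5% stretch, typical of marginal/basal chords.
rho: 1.1
terms:
  - {mu: 800.0, alpha: 14.0}
  - {mu: 100.0, alpha: 6.0}
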