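# Versioned calibration constants of the parametric annuloplasty ring
# families.  Nominal size = intercommissural dimension [mm].
#
# area_coeff maps nominal size -> (enclosed area)/(size^2), the projected
# area of the ring loop on its least-squares plane.  The coefficients were
# calibrated once against published post-annuloplasty annular areas for
# these two commercial families and are then frozen; the planform fullness
# exponent is solved at build time so each ring hits its coefficient
# exactly.
version: 1
classic:
  sl_ratio: 0.75          # septal-lateral / size (planar D-shape)
  anterior_fraction: 0.40 # anterior share of the septal-lateral depth
  indent_ratio: 0.0
  elevation_ratio: 0.0
  area_coeff:
    32: 0.5804199
    34: 0.5704758
    36: 0.5641975
    38: 0.5620983
    40: 0.5579188
geoform:
  sl_ratio: 0.45          # midline septal-lateral / size
  anterior_fraction: 0.40
  lobe_sl_ratio: 0.75     # posterior lateral lobes extend to this SL depth
  indent_width_rad: 0.45  # angular width of the mid-posterior indentation
  elevation_ratio: 0.20   # posterior elevation / size
  elevation_width_rad: 0.80
  area_coeff:
    32: 0.4726934
    34: 0.4726934
    36: 0.4726929
    38: 0.4726939
    40: 0.4726934
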