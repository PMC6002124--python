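"""Unit conventions.

The package uses one consistent unit set throughout:

========  ========
quantity  unit
========  ========
length    mm
stress    kPa
force     mN   (1 kPa * mm^2 = 1 mN)
pressure  kPa  (accepted from config in mmHg, converted on load)
time      ms   (pseudo-time of the dynamic-relaxation solver)
density   g/cm^3 in parameter files, converted to mg/mm^3 internally
========  ========
"""

MMHG_TO_KPA = 0.1333224

#: systolic transvalvular pressure used for valve closure, mmHg
DEFAULT_CLOSURE_PRESSURE_MMHG = 114.0


def mmhg_to_kpa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to kPa (114 mmHg -> 15.1987... kPa)."""
    return p_mmhg * MMHG_TO_KPA
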