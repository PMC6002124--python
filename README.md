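# mvrepair

Finite-element simulation of **undersized ring annuloplasty** and
**papillary-muscle relocation (PMR)** on a synthetic regurgitant mitral
valve.

Functional mitral regurgitation (FMR) — a leaking mitral valve caused by
ventricular dilation rather than leaflet disease — is commonly treated by
implanting an undersized annuloplasty ring, sometimes with adjunct
relocation of the anterior papillary muscle toward the left trigone. This
package provides a desk-scale, fully scripted pipeline for studying how
ring family, ring size and PMR change valve closure:

* a **parametric generator** for a labelled mitral apparatus (saddle
  annulus, anterior/posterior leaflets with scallop labels A1–A3/P1–P3,
  branched chordae from two papillary-muscle tip origins) emulating a
  dilated FMR state: annular area ≈ 945 mm², intercommissural ≈ 39 mm,
  septal-lateral ≈ 33.5 mm, eight pre-shortened posterior chordal origins
  and a posterior-lateral (P1–P2) coaptation deficiency;
* an **anisotropic hyperelastic membrane model** for the leaflets
  (Holzapfel-type with two fiber families and dispersion κ),

  W = C₁₀(e^{C₀₁(Ī₁−3)} − 1) + k₁/(2k₂) Σᵢ (e^{k₂[κĪ₁+(1−3κ)Ī₄ᵢ−1]²} − 1) + (1/D)(J−1)²,

  with exact incompressible plane stress, plus tension-only Ogden cable
  chordae, σ(λ) = Σ μᵢ(λ^{αᵢ} − λ^{−αᵢ/2});
* a **quasi-static explicit solver** (dynamic relaxation with mass scaling
  and kinetic damping) with follower pressure loading and penalty leaflet
  contact;
* the three-step **virtual repair protocol**: chordal pretension →
  ring suturing (18 annulus node clusters displaced onto planar "classic"
  or 3-D "geoform" ring curves) → optional 5 mm PMR → systolic closure at
  114 mmHg;
* a **measurement suite**: annular dimensions, projected regurgitant
  orifice area with scallop-sector labels, A2–P2 coaptation depth/length
  and tenting area, leaflet contact force/area, papillary distances, and
  midsection-patch stress/strain statistics.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
from mvrepair import build_valve, ProcedurePlan, run_case, compute_metrics
from mvrepair.metrics import annulus_measurements, percent_reduction

valve, chordae = build_valve()                    # default FMR state, seed 0
baseline = run_case(valve, chordae, ProcedurePlan(ring=None))
repaired = run_case(valve, chordae, ProcedurePlan(ring=("classic", 38)),
                    pretension=baseline.pretension)

base = compute_metrics(baseline.closed, valve)
post = compute_metrics(repaired.closed, valve)
area0 = annulus_measurements(baseline.pretension.state, valve)[2]
area1 = annulus_measurements(repaired.post_repair, valve)[2]
print(f"baseline orifice {base.orifice_area_mm2:.1f} mm^2 in {base.orifice_sectors}")
print(f"annular area reduction {percent_reduction(area0, area1):.2f} %")
print(f"contact force {base.contact_force_total_mN:.0f} -> "
      f"{post.contact_force_total_mN:.0f} mN")
```

prints (seed 0):

```
baseline orifice 27.2 mm^2 in P2+P1
annular area reduction 14.08 %
contact force 4060 -> 6311 mN
```

i.e. the untreated valve leaks through a posterior-lateral orifice; a
size-38 planar ring shrinks the annular area by 14.08% (the ring curves are
calibrated so the size ladder reproduces the published post-annuloplasty
annular areas) and raises the total leaflet closing force by ~55%.
Downsizing further (classic 32) closes the orifice to 1.6 mm² and adjunct
PMR eliminates it.

The same pipeline is scriptable from the shell:

```bash
mvrepair generate --seed 17 --out valve_dir/
mvrepair simulate --ring classic:38 --pmr --out case_dir/
mvrepair sweep --rings "classic:32,34,36,38,40 geoform:36,38" --pmr both --out sweep_dir/
mvrepair measure case_dir/
mvrepair report sweep_dir/
```

Each case directory contains the deformed surface (`.obj` and legacy
`.vtk` with stress/strain cell data), chordae tensions (`chordae.json`),
the metrics row (`metrics.csv`/`.json`) and a manifest recording the seed,
configuration hash and solver residuals.

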