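# Methods

`mvrepair` simulates undersized ring annuloplasty and papillary-muscle
relocation (PMR) on a synthetic regurgitant mitral valve. This note records
the model, its numerical treatment, the choices made where the design was
genuinely open, and what the synthetic study does and does not show about
real valves.

## The mechanical model

**Leaflets.** The anterior (AML) and posterior (PML) mitral leaflets are
thin anisotropic hyperelastic membranes. The strain energy is of
Holzapfel type with an exponential isotropic matrix and two exponential
fiber families at ±θ to the local circumferential direction, with a
dispersion parameter κ ∈ [0, 1/3]:

W = C10·(exp(C01·(Ī₁−3)) − 1)
  + k1/(2k2) · Σᵢ (exp(k2·(κĪ₁ + (1−3κ)Ī₄ᵢ − 1)²) − 1)
  + (1/D)·(J−1)²

A fiber family contributes only while its pseudo-invariant argument is
tensile (the standard switch preventing compressive fiber stiffening).
Membranes use the exact incompressible plane-stress reduction: the
through-thickness stretch follows from J = 1 and the reaction pressure is
eliminated in closed form, so the normal stress vanishes identically and
the volumetric penalty D never enters the leaflet response (it is retained
for completeness in the 3-D energy only).

Leaflet parameters (see `src/mvrepair/data/`): the published ventricular
parameter set is shipped verbatim in `lv_printed.yaml` and used in
verification; the **leaflet defaults are artifact choices, not
patient-derived** — anterior stiffer than posterior, with the exponential
terms tuned so membrane strains at 114 mmHg stay in a physiological
0.15–0.35 band and the tissue "locks" beyond ~15% stretch (without
lock-in, a bending-free membrane balloons several millimetres above the
annular plane between chord insertions, which real leaflets do not do).
Thickness: AML 1.3 mm, PML 1.0 mm.

**Chordae.** Two-node cable elements with a two-term incompressible Ogden
law, uniaxial, tension-only: σ(λ) = Σ μᵢ(λ^αᵢ − λ^(−αᵢ/2)), force =
σ·A_ref/λ. The default set gives a small-strain modulus ≈ 17 MPa with
strong stiffening above ~5% stretch, in the range reported for
marginal/basal chords; compliant chords (≲1 MPa) let the free edges ride
up to the annular plane and destroy tenting.

**Pressure.** A follower load on the ventricular leaflet surfaces: per
face, f = p × current vector area, lumped equally to the three nodes. The
closure pressure of 114 mmHg converts to 15.1987 kPa (1 mmHg =
0.1333224 kPa). Units are mm / kPa / mN / ms throughout (1 kPa·mm² = 1 mN).

**Contact.** Node-to-triangle penalty contact between the two leaflets,
resolved from both directed sides, active within a shell of half the
summed thicknesses. Because the leaflets are continuous tissue at the
commissures, mesh regions adjacent there lie inside the nominal shell in
the stress-free reference; each node's activation distance is therefore
clamped to 80% of its reference clearance, which leaves natural neighbours
force-free at rest while still resisting interpenetration. "Rough"
coaptation contact adds an elastic tangential anchor fixed when a pair
activates; no attraction is ever applied. The penalty force is
quadratically regularized over the first 15% of the shell — without this
band, the kink of the force law at activation sustains limit cycles of
boundary nodes under kinetic damping and dynamic relaxation stalls.
Default penalty 800 kPa/mm keeps residual penetration well under the
leaflet thickness while the transmitted force, set by statics, is
insensitive to the penalty (checked by a doubling test: < 1% change).

## The synthetic apparatus

The generator (`mvrepair.valve`) builds a saddle-shaped D-annulus whose
projected area, intercommissural (IC) and septal-lateral (SL) spans hit
the dilated patient targets exactly (area 944.693 mm², IC 39.1 mm, SL
33.51 mm; the planform fullness exponent is solved for the area). The
saddle height defaults to 2 mm — FMR annuli are flattened. Leaflets are
lofted from the annulus as a continuous skirt (shared commissure columns)
with material heights 21 mm (A2) and 13 mm (P2), tapering to ~8–9 mm at
the commissures.

The functional-regurgitation state is encoded by four ingredients:

1. **Tethered posterior chords**: the 8 posteromedial-PM (PPM) chordal
   origins are pre-shortened toward the annular plane by 3–6 mm (graded,
   largest for the P1/P2-serving groups). The pretension stage displaces
   them back, generating the tethering tension.
2. **Anterior-PM (APM) chord prestretch** (13%): the dilated ventricle
   displaces the APM apically/laterally, leaving its chords tight — the
   "tethering near the anterior PM" component of the disease.
3. **A P1 height deficit** (4.5 mm, Gaussian in the annular angle around
   0.70π): the posterior-lateral scallop deficiency.
4. **Dilated-state PM tips** at (−8, 18, −35) and (−10, −16, −30) mm in
   the annulus-centred frame (+x mid-anterior, +z atrial).

Chord rest lengths are sized so each chord tree goes taut exactly when its
insertions reach a nominal *closed* leaflet position (descent tilted 64°
from the annular normal) while its origin sits at the systolic PM
location — chordae are sized to carry the closed valve, which is their
physiological function. Tether shortening and APM prestretch then act
relative to that taut reference. Chordal topology: per PM, 6 marginal
origins (each feeding a branch node with 3 free-edge insertions) plus one
AML strut and one posterior basal origin; territories split at annular
angle 0.72π, so the posterior PM carries the entire posterior-lateral
margin. Systolic PM motion: 4 mm toward the annular centroid, assumed
unchanged by treatment.

The seed adds smoothed ±2% variability to leaflet heights, ±4% to
tethering magnitudes and ±0.5 mm to PM tips; annulus targets are never
jittered. Identical parameters (including seed) give bit-identical
geometry.

## The procedure pipeline

1. **Pretension** — tethered origins ramped to their true positions,
   annulus and other origins fixed; reaction forces recorded at *every*
   origin (the 8 tethered ones are the reported surface).
2. **Annuloplasty** — the ring curve (parametric family, see below) is
   aligned: least-squares planes parallel, mid-anterior/posterior azimuth
   matched, the remaining slide along the SL axis minimizing the
   anterior-third arc distance (the anterior annulus must move least).
   Every annulus node is then displaced onto the ring by arc-length-
   proportional mapping (the 18 uniform clusters of 3 land exactly on the
   18 uniform ring targets; prescribing only the clusters leaves the
   bending-free annulus ragged between them, so the whole suture line is
   driven). The chordal-origin constraints are replaced by constant point
   loads equal to the recorded reactions — the release itself is exactly
   equilibrium-preserving — plus a weak elastic anchor (40 mN/mm) standing
   in for the compliance of the ventricular wall the chords are tied to.
3. **PMR** (optional) — all APM origins displaced 5 mm along the unit
   vector from the current APM tip to the left trigone; annulus and PPM
   origins fixed. ("Anteriorly and towards the lateral trigone" is
   operationalized as this single direction.)
4. **Closure** — pressure ramped to 114 mmHg on the ventricular faces;
   chordal origins follow their diastole→systole displacement from their
   current (post-repair) positions; the annulus is held fixed (ring shape
   post-repair; native diastolic geometry for the untreated baseline).

## Ring families

Nominal size = intercommissural dimension. The planar D-shaped family
("classic") has SL = 0.75 × size; the 3-D family ("geoform") has a midline
SL of 0.45 × size, posterior lateral lobes reaching 0.75 × size with a
mid-posterior anterior indentation of 0.30 × size, and a posterior
elevation bump of 0.20 × size. Per-size enclosed-area coefficients
(`data/rings.yaml`, versioned) were calibrated once against published
post-annuloplasty annular areas; at build time the planform fullness
exponent is solved so the loop's projected area matches its coefficient
exactly. A planform with a full-width SL of 0.45 × size geometrically
*cannot* enclose 0.473 × size² (it would exceed its own bounding box),
which is why the 3-D family must carry posterior lobes plus a midline
indentation — consistent with the commercial ring's kidney-like shape.

## Dynamic relaxation

Equilibria are found by explicit central-difference pseudo-time
integration with per-node mass scaling and kinetic damping: nodal masses
follow a generous tangent-stiffness bound (membrane + cable + contact
+ anchors, safety 1.35), so the unit pseudo-time step is always stable;
velocities are zeroed whenever the kinetic energy peaks, a small viscous
decay (1%/step) removes wrinkling chatter, and velocities are capped at
0.08 mm/step. Prescribed displacements and pressure ramp linearly over
1600 steps. Convergence: RMS residual force on free nodes below 0.8% of
the RMS force *throughput* (the per-node sum of absolute force
contributions), a scale-invariant criterion, or below an absolute floor of
0.02 mN; non-convergence warns (or raises in strict mode) with the
residual history. The integration is fully deterministic — serial
accumulation in fixed element order (the numba kernels mirror the numpy
reference path to machine precision, asserted by a test).

Typical stage cost at the default resolution (64 circumferential stations,
6 radial divisions ≈ 450 leaflet nodes, 768 membrane elements, ~100
cables): 1600–8000 steps, a few seconds. A full case (pretension →
annuloplasty → PMR → closure) runs in 10–25 s on one CPU; the default
resolution was chosen so the full 15-case repair matrix completes in a few
minutes while annular-area discretization error stays below 0.2%.

## Measurements

All metrics are computed from converged states and are rigid-motion
invariant. Annular area is the loop polygon projected on its least-squares
plane; IC/SL are landmark distances. The regurgitant orifice is the part
of the annulus polygon covered by neither projected leaflet (shapely
boolean operations; ±0.15 mm morphological opening removes mesh-hairline
slivers; components labelled by angular scallop sector and validated
against a raster oracle). Coaptation depth/length and tenting area are
measured on the A2–P2 cut plane: a point is "coapted" when the leaflet
mid-surface sections are within the contact shell plus 25% of the mean
thickness (the coaptation threshold is not defined in the source study;
this is the package's convention). Contact force/area sum the anterior
side of the penalty interface, with current-configuration tributary areas.
The APM–MA distance is from the APM tip (tracked as the mean displacement
of the APM origins) to the annular least-squares plane. Patch statistics
(average *and* median, both reported since the source literature uses
both) cover elements fully inside a 10×10 mm AML and 9×9 mm PML midsection
patch; stresses are max-principal Cauchy values from the membrane
deformation gradients.

## What the synthetic study shows — and does not

The generator emulates the *state* of one dilated-ventricle patient, not
the patient: absolute magnitudes (contact force in newtons, stress surges
of thousands of percent) depend on the unavailable image-derived geometry
and tissue constants and are out of quantitative scope. What carries over
are (i) the percentage-reduction arithmetic and the ring-area calibration
chain, which reproduce the published annular-area reduction column within
tolerance because the ring curves are calibrated to enclosed area, and
(ii) directional treatment responses: every ring increases the total
closing force and the APM–MA distance; Classic downsizing monotonically
shrinks the orifice; adjunct PMR pulls the APM tip toward the annulus,
reduces the inter-PM distance and the lateral orifice and raises the
closing force.

Two directional responses of the source study are **not** reproduced by
this reduced model and are reported as such rather than tuned away:

* *PMR lowering the posterior-leaflet patch stress.* Here the chordae act
  as transverse supports of the pressurized posterior sail; releasing the
  APM chords (which is what relocating the APM toward the trigone does to
  chord kinematics) always deepens the sail and raises membrane tension,
  even though the radial tether strain in the patch drops as intended.
  The reported relief evidently runs through ventricular-wall mechanics —
  the volumetric ventricle is deliberately out of scope here, reduced to
  kinematic landmarks, dead loads and a lumped anchor stiffness.
* *Perfect monotonicity of the A2–P2 coaptation length* under Classic
  downsizing: the trend holds but single-size inversions of ~0.3 mm occur;
  the cut-plane length is the most discretization-sensitive metric in the
  suite (section resolution ≈ 1 mm at default mesh density).

Other known limitations: no bending stiffness (membrane elements), so
leaflet buckling patterns are not meaningful; no fluid–structure
interaction (uniform static pressure only); no chordal rupture/cutting;
the annulus is kinematically driven rather than carried by atrial tissue;
and the commissural continuity of the leaflet skirt is a geometric
idealization.
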