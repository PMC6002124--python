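"""Outcome measures of a simulated valve configuration.

All quantities are computed from a converged :class:`~mvrepair.fe.SimState`
plus the labelled valve model: annular dimensions, regurgitant orifice area
(projected), A2-P2 cut-plane coaptation depth/length and tenting area,
leaflet contact force/area, papillary-muscle distances, and midsection-patch
stress/strain statistics.  Every metric is invariant under rigid motions of
the state.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geometry import Plane, least_squares_plane, polygon_area_2d
from .valve import SCALLOPS, ValveModel

#: a cut-plane point counts as coapted when the leaflet mid-surfaces are
#: within the contact shell plus this fraction of the mean thickness
COAPT_TOL_FACTOR = 0.25

__all__ = [
    "MetricsReport",
    "annulus_measurements",
    "percent_reduction",
    "cutplane_metrics",
    "orifice_area_2d",
    "contact_summary",
    "pm_distances",
    "patch_stats",
    "compute_metrics",
]


@dataclass
class MetricsReport:
    """All scalar outcome measures of one simulated configuration."""

    intercommissural_mm: float
    septal_lateral_mm: float
    annular_area_mm2: float
    orifice_area_mm2: float
    orifice_sectors: str            # '+'-joined scallop sectors of the gaps
    tenting_area_mm2: float
    coaptation_depth_mm: float
    coaptation_length_mm: float
    contact_force_total_mN: float
    contact_force_max_mN: float
    contact_area_mm2: float
    apm_ma_mm: float
    inter_pm_mm: float
    aml_stress_avg_kPa: float
    aml_stress_median_kPa: float
    aml_strain_avg: float
    aml_strain_median: float
    pml_stress_avg_kPa: float
    pml_stress_median_kPa: float
    pml_strain_avg: float
    pml_strain_median: float

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        d = self.to_dict()
        for k, v in d.items():
            if k == "orifice_sectors":
                continue
            if not np.isfinite(v):
                raise ValueError(f"metric {k} is not finite")
        nonneg = [k for k in d if k.endswith(("_mm", "_mm2", "_mN"))]
        for k in nonneg:
            if d[k] < -1e-9:
                raise ValueError(f"metric {k} is negative: {d[k]}")
        if self.contact_force_total_mN + 1e-9 < self.contact_force_max_mN:
            raise ValueError("total contact force below max nodal force")


# ---------------------------------------------------------------- annulus

def annulus_measurements(state, valve: ValveModel) -> tuple[float, float, float]:
    """(intercommissural distance, septal-lateral distance, annular area).

    IC and SL are Euclidean distances between the commissure landmarks and
    the mid-anterior/mid-posterior landmarks; the area is that of the
    annulus polygon projected on its least-squares plane.
    """
    x = state.x if hasattr(state, "x") else state
    lm = valve.landmarks
    for need in ("lateral_commissure", "septal_commissure", "saddle_horn", "mid_posterior"):
        if need not in lm:
            raise ValueError(f"missing annulus landmark {need!r}")
    ic = float(np.linalg.norm(x[lm["lateral_commissure"]] - x[lm["septal_commissure"]]))
    sl = float(np.linalg.norm(x[lm["saddle_horn"]] - x[lm["mid_posterior"]]))
    ann = x[valve.annulus_loop]
    plane = least_squares_plane(ann)
    area = polygon_area_2d(plane.to_2d(ann))
    return ic, sl, area


def percent_reduction(baseline: float, value: float) -> float:
    """100 * (baseline - value) / baseline, reported to 2 decimals
    (negative when the value exceeds the baseline)."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return round(100.0 * (baseline - value) / baseline, 2)


# ---------------------------------------------------------------- cut plane

def _leaflet_section(x: np.ndarray, valve: ValveModel, region: int,
                     plane_point: np.ndarray, plane_normal: np.ndarray,
                     u_dir: np.ndarray, w_dir: np.ndarray) -> np.ndarray:
    """Ordered 2-D polyline (u, w) of one leaflet's intersection with the
    cut plane, from the annulus end to the free edge."""
    tris = valve.tris[valve.tri_region == region]
    p = x[tris]  # (m, 3, 3)
    d = (p - plane_point) @ plane_normal
    segs = []
    for e in range(len(tris)):
        de = d[e]
        pts = [p[e, i] for i in range(3) if de[i] == 0.0]
        for (i, j) in ((0, 1), (1, 2), (2, 0)):
            if de[i] * de[j] < 0.0:
                t = de[i] / (de[i] - de[j])
                pts.append(p[e, i] + t * (p[e, j] - p[e, i]))
        if len(pts) >= 2:
            segs.append((pts[0], pts[1]))
    if not segs:
        raise ValueError("leaflet does not intersect the cut plane")

    def to2d(q):
        rel = q - plane_point
        return np.array([rel @ u_dir, rel @ w_dir])

    # drop duplicate/degenerate segments (adjacent element strips can emit
    # the same on-plane mesh edge twice)
    seen = set()
    segs2 = []
    for a, b in segs:
        a2, b2 = to2d(a), to2d(b)
        if np.hypot(*(a2 - b2)) < 1e-9:
            continue
        key = tuple(sorted((tuple(np.round(a2, 6)), tuple(np.round(b2, 6)))))
        if key in seen:
            continue
        seen.add(key)
        segs2.append((a2, b2))
    # chain segments endpoint-to-endpoint starting from the annulus end
    # (largest |u|, i.e. nearest the annulus ring)
    pts_all = [q for s in segs2 for q in s]
    start_idx = int(np.argmax([abs(q[0]) for q in pts_all]))
    chain = [pts_all[start_idx]]
    remaining = list(segs2)
    cur = chain[0]
    tol = 1e-6
    while remaining:
        best = None
        bestd = np.inf
        for k, (a, b) in enumerate(remaining):
            da = np.hypot(*(a - cur))
            db = np.hypot(*(b - cur))
            if min(da, db) < bestd:
                bestd = min(da, db)
                best = (k, a if da <= db else b, b if da <= db else a)
        if best is None or bestd > 2.0:  # disconnected leftover slivers
            break
        k, near, far = best
        remaining.pop(k)
        if bestd > tol:
            chain.append(near)
        chain.append(far)
        cur = far
    return np.asarray(chain)


def _resample_polyline(poly: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(poly[:1], n, axis=0)
    t = np.linspace(0.0, s[-1], n)
    out = np.empty((n, poly.shape[1]))
    for c in range(poly.shape[1]):
        out[:, c] = np.interp(t, s, poly[:, c])
    return out


def cutplane_metrics(state, valve: ValveModel,
                     n_samples: int = 400) -> tuple[float, float, float]:
    """(coaptation depth [mm], coaptation length [mm], tenting area [mm^2])
    on the A2-P2 section.

    The cut plane passes through the annular centroid, contains the annular
    normal and the mid-anterior/mid-posterior (A2/P2) landmark direction.
    Coaptation length is the arc length of the anterior cross-section whose
    distance to the posterior cross-section is within the contact shell plus
    ``COAPT_TOL_FACTOR`` x mean thickness; depth is the distance from the
    annular plane down to the atrial-most coapted point; tenting area is the
    area enclosed between the annular-plane chord and the two leaflet
    sections above the coaptation zone (or above the free-edge gap when the
    section does not coapt).
    """
    x = state.x if hasattr(state, "x") else state
    ann = x[valve.annulus_loop]
    plane = least_squares_plane(ann)
    c = plane.point
    n = plane.normal
    sl = x[valve.landmarks["saddle_horn"]] - x[valve.landmarks["mid_posterior"]]
    sl = sl - (sl @ n) * n
    u_dir = sl / np.linalg.norm(sl)
    m = np.cross(n, u_dir)  # cut-plane normal

    aml = _leaflet_section(x, valve, 0, c, m, u_dir, n)
    pml = _leaflet_section(x, valve, 1, c, m, u_dir, n)
    aml = _resample_polyline(aml, n_samples)
    pml = _resample_polyline(pml, max(n_samples, 200))

    t_a = float(valve.thickness[valve.tri_region == 0].mean())
    t_p = float(valve.thickness[valve.tri_region == 1].mean())
    tol = 0.5 * (t_a + t_p) + COAPT_TOL_FACTOR * 0.5 * (t_a + t_p)

    d2 = np.linalg.norm(aml[:, None, :] - pml[None, :, :], axis=2)
    dmin = d2.min(axis=1)
    coapted = dmin <= tol

    seg = np.linalg.norm(np.diff(aml, axis=0), axis=1)
    mid = 0.5 * (coapted[1:].astype(float) + coapted[:-1].astype(float))
    length = float(np.sum(seg * mid))

    if np.any(coapted):
        w_top = float(aml[coapted, 1].max())
        top_idx = int(np.nonzero(coapted)[0][np.argmax(aml[coapted, 1])])
        a_cut = aml[: top_idx + 1]
        j = int(np.argmin(d2[top_idx]))
        p_cut = pml[: j + 1]
    else:
        tip_a = aml[-1]
        tip_p = pml[-1]
        w_top = float(0.5 * (tip_a[1] + tip_p[1]))
        a_cut = aml
        p_cut = pml
    depth = max(0.0, -w_top)

    # tenting polygon: annulus chord -> AML section -> (gap or coaptation
    # point) -> reversed PML section -> back to the chord
    ring_pts = np.vstack([a_cut, p_cut[::-1]])
    poly = Polygon([tuple(q) for q in ring_pts])
    if not poly.is_valid:
        poly = poly.buffer(0)
    # clip to below the annular plane (w <= 0): tenting is sub-annular
    lo = float(min(ring_pts[:, 1].min(), -1.0)) - 1.0
    umin, umax = ring_pts[:, 0].min() - 1.0, ring_pts[:, 0].max() + 1.0
    half = Polygon([(umin, lo), (umax, lo), (umax, 0.0), (umin, 0.0)])
    tenting = float(poly.intersection(half).area)
    return depth, length, tenting


# ----------------------------------------------------------------- orifice

def _sector_of_angle(th: float) -> str:
    th = np.mod(th, 2 * np.pi)
    bounds = [
        (0, np.pi / 6, "A2"), (np.pi / 6, np.pi / 2, "A1"),
        (np.pi / 2, 5 * np.pi / 6, "P1"), (5 * np.pi / 6, 7 * np.pi / 6, "P2"),
        (7 * np.pi / 6, 3 * np.pi / 2, "P3"), (3 * np.pi / 2, 11 * np.pi / 6, "A3"),
        (11 * np.pi / 6, 2 * np.pi, "A2"),
    ]
    for lo, hi, name in bounds:
        if lo <= th < hi:
            return name
    return "A2"


def orifice_area_2d(state, valve: ValveModel,
                    min_component_area: float = 0.5) -> tuple[float, list[str]]:
    """Projected regurgitant orifice area [mm^2] and its scallop sectors.

    Both leaflet meshes are projected onto the annular least-squares plane;
    the orifice is the part of the annulus polygon covered by neither
    projection (polygon boolean operations, hairline slivers from mesh
    discretization removed by a +-0.15 mm morphological open).
    """
    x = state.x if hasattr(state, "x") else state
    ann = x[valve.annulus_loop]
    plane = least_squares_plane(ann)
    basis = plane.basis()
    ann2 = plane.to_2d(ann, basis)
    ann_poly = Polygon([tuple(q) for q in ann2])
    if not ann_poly.is_valid:
        ann_poly = ann_poly.buffer(0)

    tri2 = plane.to_2d(x[valve.tris].reshape(-1, 3), basis).reshape(-1, 3, 2)
    polys = []
    for t in tri2:
        if abs(np.cross(t[1] - t[0], t[2] - t[0])) < 1e-9:
            continue
        polys.append(Polygon([tuple(q) for q in t]))
    cover = unary_union(polys)
    raw = ann_poly.difference(cover)
    # a +-0.15 mm morphological open identifies the significant components
    # (killing mesh-edge hairlines); areas are then measured on the raw
    # geometry so jagged component boundaries are not eroded
    orifice = raw.buffer(-0.15).buffer(0.15)

    # sector labelling by angle about the annular centroid, anchored at the
    # mid-anterior landmark direction with the lateral commissure at +90 deg
    a2 = plane.to_2d(x[valve.landmarks["saddle_horn"]], basis)
    lat = plane.to_2d(x[valve.landmarks["lateral_commissure"]], basis)
    ref = a2 / np.linalg.norm(a2)
    perp = np.array([-ref[1], ref[0]])
    if perp @ lat < 0:
        perp = -perp

    area = 0.0
    comp: list[tuple[float, str]] = []
    geoms = getattr(orifice, "geoms", [orifice]) if not orifice.is_empty else []
    for g in geoms:
        if g.area < min_component_area:
            continue
        a = raw.intersection(g.buffer(0.3)).area
        area += a
        rp = np.asarray(g.representative_point().coords[0])
        th = np.arctan2(rp @ perp, rp @ ref)
        comp.append((a, _sector_of_angle(th)))
    # sectors ordered by decreasing component area (rigid-motion invariant)
    comp.sort(key=lambda c: -c[0])
    seen = set()
    sectors = [name for _, name in comp if not (name in seen or seen.add(name))]
    return float(area), sectors


# ----------------------------------------------------------------- contact

def contact_summary(state, valve: ValveModel) -> tuple[float, float, float]:
    """(total contact force [mN], max nodal force [mN], contact area [mm^2]),
    summed over the anterior-leaflet side of the coaptation interface; the
    area is the current-configuration tributary area of the contact-active
    nodes."""
    x = state.x
    f = state.contact_force
    aml_nodes = np.unique(valve.tris[valve.tri_region == 0].ravel())
    mags = np.linalg.norm(f[aml_nodes], axis=1)
    active = aml_nodes[mags > 1e-9]
    total = float(mags.sum())
    fmax = float(mags.max(initial=0.0))

    if len(active) == 0:
        return 0.0, 0.0, 0.0
    p = x[valve.tris]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    trib = np.zeros(len(x))
    np.add.at(trib, valve.tris.ravel(), np.repeat(areas / 3.0, 3))
    return total, fmax, float(trib[active].sum())


def pm_distances(state, valve: ValveModel) -> tuple[float, float]:
    """(inter-PM distance, APM tip to annular least-squares plane) [mm]."""
    tips = getattr(state, "pm_tips", None) or {}
    if "APM" not in tips or "PPM" not in tips:
        raise ValueError("papillary tips are not tracked in this state")
    x = state.x if hasattr(state, "x") else state
    plane = least_squares_plane(x[valve.annulus_loop])
    inter = float(np.linalg.norm(tips["APM"] - tips["PPM"]))
    apm_ma = float(abs(plane.signed_distance(tips["APM"])))
    return inter, apm_ma


def patch_stats(state, valve: ValveModel) -> dict:
    """Average and median max-principal Cauchy stress [kPa] and Green strain
    over the midsection patch elements of each leaflet."""
    out = {}
    for leaflet in ("AML", "PML"):
        els = valve.patch_elements(leaflet)
        if len(els) == 0:
            raise ValueError(f"empty midsection patch for {leaflet}")
        s = state.tri_stress_max[els]
        e = state.tri_strain_max[els]
        out[leaflet] = {
            "stress_avg": float(s.mean()),
            "stress_median": float(np.median(s)),
            "strain_avg": float(e.mean()),
            "strain_median": float(np.median(e)),
        }
    return out


def compute_metrics(state, valve: ValveModel) -> MetricsReport:
    """Assemble the full report for one converged configuration."""
    ic, sl, area = annulus_measurements(state, valve)
    orifice, sectors = orifice_area_2d(state, valve)
    depth, length, tenting = cutplane_metrics(state, valve)
    ftot, fmax, carea = contact_summary(state, valve)
    inter_pm, apm_ma = pm_distances(state, valve)
    ps = patch_stats(state, valve)
    rep = MetricsReport(
        intercommissural_mm=ic,
        septal_lateral_mm=sl,
        annular_area_mm2=area,
        orifice_area_mm2=orifice,
        orifice_sectors="+".join(sectors),
        tenting_area_mm2=tenting,
        coaptation_depth_mm=depth,
        coaptation_length_mm=length,
        contact_force_total_mN=ftot,
        contact_force_max_mN=fmax,
        contact_area_mm2=carea,
        apm_ma_mm=apm_ma,
        inter_pm_mm=inter_pm,
        aml_stress_avg_kPa=ps["AML"]["stress_avg"],
        aml_stress_median_kPa=ps["AML"]["stress_median"],
        aml_strain_avg=ps["AML"]["strain_avg"],
        aml_strain_median=ps["AML"]["strain_median"],
        pml_stress_avg_kPa=ps["PML"]["stress_avg"],
        pml_stress_median_kPa=ps["PML"]["stress_median"],
        pml_strain_avg=ps["PML"]["strain_avg"],
        pml_strain_median=ps["PML"]["strain_median"],
    )
    rep.validate()
    return rep
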