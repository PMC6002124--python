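"""The virtual-repair protocol: pretension, ring annuloplasty, papillary-
muscle relocation (PMR), and systolic closure, as composable stages.

Protocol summary
----------------
1. *Pretension*: the 8 tethered posteromedial-PM chordal origins are
   displaced from their shortened diastolic positions back to their true
   (dilated) locations, generating the tethering tension; the reaction force
   at every chordal origin is recorded at equilibrium.
2. *Annuloplasty*: the ring curve is aligned with the annulus (parallel
   least-squares planes, matched mid-anterior/mid-posterior azimuth,
   anterior overlap maximized), 18 clusters of 3 adjacent annulus nodes are
   displaced onto 18 uniformly spaced ring targets, and the chordal-origin
   displacement constraints are replaced by constant point loads equal to
   the recorded pretension reactions (so the release itself leaves the
   system in equilibrium).
3. *PMR* (optional): all anterolateral-PM chordal origins are displaced
   5 mm along the unit vector from the current APM tip toward the left
   trigone; annulus and the other origins stay fixed.
4. *Closure*: a transvalvular pressure (default 114 mmHg) is ramped onto
   the ventricular leaflet surfaces while the chordal origins follow their
   diastole-to-systole trajectory and the annulus is held fixed (at the
   ring shape post-repair, or at the native diastolic geometry for the
   untreated baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .fe import FEModel, SimState, SolverConfig, Stage, solve_quasistatic
from .geometry import (
    Plane,
    axis_angle_rotation,
    least_squares_plane,
    polyline_arclength,
    resample_closed_curve,
    rotation_between,
)
from .materials import load_hgo_params, load_ogden_params, data_path
from .rings import RingGeometry, build_ring
from .units import mmhg_to_kpa
from .valve import ChordaeNetwork, ValveModel

N_CLUSTERS = 18
CLUSTER_SIZE = 3

#: stiffness (mN/mm) of the elastic anchor holding each released chordal
#: origin near its pre-annuloplasty position, emulating the compliance of
#: the ventricular wall the chords are tied to
LV_ANCHOR_K = 40.0

__all__ = [
    "ProcedurePlan",
    "PretensionResult",
    "AnnulusCorrespondence",
    "default_materials",
    "make_model",
    "least_squares_plane",
    "run_pretension",
    "align_ring",
    "build_annulus_correspondence",
    "run_annuloplasty",
    "run_pmr",
    "run_closure",
    "run_case",
    "CaseResult",
]


@dataclass
class ProcedurePlan:
    """One repair configuration: which ring (or none), PMR on/off, closure
    pressure."""

    ring: tuple[str, int] | None = None
    pmr: bool = False
    pmr_magnitude: float = 5.0
    closure_pressure_kpa: float = mmhg_to_kpa(114.0)

    def __post_init__(self) -> None:
        if self.pmr and self.pmr_magnitude <= 0:
            raise ValueError("pmr_magnitude must be > 0 when PMR is enabled")
        if self.closure_pressure_kpa <= 0:
            raise ValueError("closure pressure must be > 0")

    @property
    def label(self) -> str:
        ring = "baseline" if self.ring is None else f"{self.ring[0]}{self.ring[1]}"
        return ring + ("_pmr" if self.pmr else "")


@dataclass
class PretensionResult:
    """Equilibrium after the tethering step plus per-origin reactions."""

    state: SimState
    reactions: np.ndarray            # (K, 3) reaction per chordal origin (mN)
    tethered_origin_ids: np.ndarray  # (8,)

    @property
    def tethered_reactions(self) -> np.ndarray:
        return self.reactions[self.tethered_origin_ids]


@dataclass
class AnnulusCorrespondence:
    """18 clusters of 3 adjacent annulus nodes paired with 18 ring targets."""

    clusters: np.ndarray  # (18, 3) node ids
    targets: np.ndarray   # (18, 3) points on the ring curve

    def cluster_nodes(self) -> np.ndarray:
        return self.clusters.ravel()


@dataclass
class CaseResult:
    plan: ProcedurePlan
    pretension: PretensionResult
    post_repair: SimState | None   # after annuloplasty (None for baseline)
    post_pmr: SimState | None
    closed: SimState
    ring: RingGeometry | None


def default_materials() -> dict:
    return {
        "anterior": load_hgo_params(data_path("leaflet_anterior.yaml")),
        "posterior": load_hgo_params(data_path("leaflet_posterior.yaml")),
        "chordae": load_ogden_params(data_path("chordae_ogden.yaml")),
    }


def make_model(valve: ValveModel, chordae: ChordaeNetwork,
               materials: dict | None = None) -> FEModel:
    return FEModel(valve, chordae, materials or default_materials())


# ----------------------------------------------------------------- pretension

def run_pretension(valve: ValveModel, chordae: ChordaeNetwork,
                   model: FEModel | None = None,
                   cfg: SolverConfig | None = None) -> PretensionResult:
    """Displace the tethered origins back to their pre-shortening positions
    and record the reaction force at every chordal origin."""
    model = model or make_model(valve, chordae)
    cfg = cfg or SolverConfig()
    teth = chordae.tethered_origin_ids
    teth_gids = model.origin_ids[teth]
    other = np.setdiff1d(np.arange(chordae.n_origins), teth)
    stage = Stage(
        fixed=np.concatenate([valve.annulus_loop, model.origin_ids[other]]),
        prescribed_ids=teth_gids,
        prescribed_targets=chordae.origins_pre_shortening[teth],
        contact=True,
    )
    st = solve_quasistatic(model, model.X0.copy(), stage, cfg)
    st.pm_tips = {"APM": valve.apm_tip.copy(), "PPM": valve.ppm_tip.copy()}
    reactions = st.reactions[model.origin_ids]
    return PretensionResult(state=st, reactions=reactions, tethered_origin_ids=teth)


# ------------------------------------------------------------ ring alignment

def align_ring(ring: RingGeometry, valve: ValveModel,
               state: SimState | None = None) -> RingGeometry:
    """Rigidly place a ring curve on the annulus.

    The ring's least-squares plane is rotated parallel to the annular plane;
    the ring's mid-anterior/mid-posterior axis is rotated into the plane
    spanned by the annular normal and the annular mid-anterior/mid-posterior
    landmarks; the remaining in-plane translation along that axis maximizes
    the overlap of the anterior third of the ring with the anterior third of
    the annulus (least squared distance).
    """
    x = state.x if state is not None else valve.nodes
    ann = x[valve.annulus_loop]
    ann_plane = least_squares_plane(ann)
    ring_plane = ring.plane()

    R1 = rotation_between(ring_plane.normal, ann_plane.normal)
    c0 = ring.curve.mean(axis=0)
    curve = (ring.curve - c0) @ R1.T

    # azimuth: ring SL axis -> annulus SL axis (projected on the plane)
    n = ann_plane.normal
    a_pt = x[valve.landmarks["saddle_horn"]]
    p_pt = x[valve.landmarks["mid_posterior"]]
    sl_ann = a_pt - p_pt
    sl_ann -= (sl_ann @ n) * n
    sl_ann /= np.linalg.norm(sl_ann)
    sl_ring = curve[ring.mid_anterior_idx] - curve[ring.mid_posterior_idx]
    sl_ring -= (sl_ring @ n) * n
    sl_ring /= np.linalg.norm(sl_ring)
    ang = np.arctan2(np.cross(sl_ring, sl_ann) @ n, sl_ring @ sl_ann)
    R2 = axis_angle_rotation(n, ang)
    curve = curve @ R2.T

    # translation: on the annular plane, constrained to the SL axis so the
    # ring landmarks stay in the annular SL plane; slide to fit the anterior
    # third arc
    t_axis = sl_ann
    mid = 0.5 * (a_pt + p_pt)
    base = mid - (ann_plane.signed_distance(mid)) * n

    nA = len(ann)
    third = nA // 3
    order = np.argsort(
        np.abs(((np.arange(nA) - valve.landmarks["saddle_horn"]) + nA // 2) % nA - nA // 2)
    )
    ant_annulus = ann[order[:third]]
    nr = len(curve)
    ring_third = np.concatenate([np.arange(-(nr // 6), nr // 6 + 1)]) % nr
    ant_ring = curve[ring_third]

    def cost(t: float) -> float:
        pts = ant_ring + base + t * t_axis
        d = pts[:, None, :] - ant_annulus[None, :, :]
        return float(np.min(np.einsum("ijk,ijk->ij", d, d), axis=1).sum())

    span = 0.6 * max(np.linalg.norm(a_pt - p_pt), 1.0)
    res = minimize_scalar(cost, bounds=(-span, span), method="bounded",
                          options={"xatol": 1e-6})
    t_best = float(res.x)
    placed = curve + base + t_best * t_axis
    return RingGeometry(ring.family, ring.nominal_size, placed,
                        ring.mid_anterior_idx, ring.mid_posterior_idx)


def build_annulus_correspondence(valve: ValveModel, ring: RingGeometry,
                                 state: SimState | None = None) -> AnnulusCorrespondence:
    """Pair 18 uniformly spaced annulus node clusters (3 adjacent nodes each)
    with 18 uniformly spaced ring targets, anchored at the mid-anterior
    landmark with a common winding."""
    x = state.x if state is not None else valve.nodes
    loop = valve.annulus_loop
    nA = len(loop)
    if nA < N_CLUSTERS * CLUSTER_SIZE:
        raise ValueError(
            f"annulus loop has {nA} nodes; {N_CLUSTERS * CLUSTER_SIZE} are "
            "needed for 18 disjoint clusters of 3"
        )
    ann = x[loop]
    plane = least_squares_plane(ann)

    # normalize both windings to counterclockwise about the annular normal
    def winding(pts: np.ndarray) -> float:
        q = pts - pts.mean(axis=0)
        u, v = plane.basis()
        xy = np.stack([q @ u, q @ v], axis=-1)
        return float(np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1]))

    ann_ccw = winding(ann) > 0

    s_ann = polyline_arclength(ann, closed=True)
    total = s_ann[-1]
    anchor = int(np.nonzero(loop == valve.landmarks["saddle_horn"])[0][0])

    clusters = np.empty((N_CLUSTERS, CLUSTER_SIZE), dtype=np.int64)
    used: set[int] = set()
    for k in range(N_CLUSTERS):
        s_target = (s_ann[anchor] + k * total / N_CLUSTERS) % total
        center = int(np.argmin(np.abs(((s_ann[:-1] - s_target + total / 2) % total) - total / 2)))
        # resolve collisions by stepping forward
        tries = 0
        while any(((center + d) % nA) in used for d in (-1, 0, 1)):
            center = (center + 1) % nA
            tries += 1
            if tries > nA:
                raise ValueError("cannot place disjoint annulus clusters")
        ids = [(center - 1) % nA, center, (center + 1) % nA]
        used.update(ids)
        clusters[k] = loop[ids]

    # ring targets uniform in arc length from the mid-anterior landmark,
    # with the ring winding matched to the annulus winding
    curve = ring.curve
    if (winding(curve) > 0) != ann_ccw:
        curve = curve[::-1]
        ma = len(curve) - 1 - ring.mid_anterior_idx
    else:
        ma = ring.mid_anterior_idx
    s_ring = polyline_arclength(curve, closed=True)
    targets = resample_closed_curve(curve, N_CLUSTERS, s0=s_ring[ma])
    return AnnulusCorrespondence(clusters=clusters, targets=targets)


# ---------------------------------------------------------------- procedures

def _update_tips(state: SimState, prev: SimState, model: FEModel,
                 chordae: ChordaeNetwork) -> None:
    tips = {}
    for name, pm in (("APM", 0), ("PPM", 1)):
        oids = model.origin_ids[chordae.origin_pm == pm]
        disp = (state.x[oids] - prev.x[oids]).mean(axis=0)
        tips[name] = prev.pm_tips[name] + disp
    state.pm_tips = tips


def run_annuloplasty(valve: ValveModel, chordae: ChordaeNetwork,
                     pretension: PretensionResult, ring: RingGeometry,
                     model: FEModel | None = None,
                     cfg: SolverConfig | None = None) -> tuple[SimState, RingGeometry]:
    """Suture the ring: displace the 18 annulus clusters onto the aligned
    ring targets while the chordal origins, released from their displacement
    constraints, carry constant point loads equal to the recorded pretension
    reactions.

    Returns the equilibrium state and the aligned ring.
    """
    model = model or make_model(valve, chordae)
    cfg = cfg or SolverConfig()
    st0 = pretension.state
    aligned = align_ring(ring, valve, st0)
    corr = build_annulus_correspondence(valve, aligned, st0)

    # the suture line is continuous: every annulus node is mapped onto the
    # ring arc-length-proportionally (the 18 clusters land on the 18 uniform
    # ring targets of the correspondence by construction)
    loop_targets = map_annulus_to_ring(valve, aligned, st0)

    loads = np.zeros_like(st0.x)
    loads[model.origin_ids] = pretension.reactions

    stage = Stage(
        fixed=np.empty(0, np.int64),
        prescribed_ids=valve.annulus_loop.astype(np.int64),
        prescribed_targets=loop_targets,
        point_loads=loads,
        contact=True,
        anchor_ids=model.origin_ids,
        anchor_ref=st0.x[model.origin_ids].copy(),
        anchor_k=LV_ANCHOR_K,
    )
    st = solve_quasistatic(model, st0.x.copy(), stage, cfg)
    st.pm_tips = dict(st0.pm_tips)
    _update_tips(st, st0, model, chordae)
    return st, aligned


def map_annulus_to_ring(valve: ValveModel, ring: RingGeometry,
                        state: SimState | None = None) -> np.ndarray:
    """Arc-length-proportional suture map: the position on the (aligned)
    ring curve for every annulus-loop node, anchored at the mid-anterior
    landmark with matched winding."""
    x = state.x if state is not None else valve.nodes
    loop = valve.annulus_loop
    nA = len(loop)
    ann = x[loop]
    plane = least_squares_plane(ann)

    def winding_ccw(pts: np.ndarray) -> bool:
        q = pts - pts.mean(axis=0)
        u, v = plane.basis()
        xy = np.stack([q @ u, q @ v], axis=-1)
        return float(np.sum(xy[:, 0] * np.roll(xy[:, 1], -1)
                            - np.roll(xy[:, 0], -1) * xy[:, 1])) > 0

    curve = ring.curve
    ma = ring.mid_anterior_idx
    if winding_ccw(curve) != winding_ccw(ann):
        curve = curve[::-1]
        ma = len(curve) - 1 - ma

    s_ann = polyline_arclength(ann, closed=True)
    anchor = int(np.nonzero(loop == valve.landmarks["saddle_horn"])[0][0])
    frac = ((s_ann[:-1] - s_ann[anchor]) % s_ann[-1]) / s_ann[-1]

    s_ring = polyline_arclength(curve, closed=True)
    total_r = s_ring[-1]
    out = np.empty((nA, 3))
    loop_curve = np.vstack([curve, curve[:1]])
    for i, f in enumerate(frac):
        t = (s_ring[ma] + f * total_r) % total_r
        k = min(int(np.searchsorted(s_ring, t, side="right")) - 1, len(loop_curve) - 2)
        w = (t - s_ring[k]) / max(s_ring[k + 1] - s_ring[k], 1e-300)
        out[i] = (1 - w) * loop_curve[k] + w * loop_curve[k + 1]
    return out


def run_pmr(state: SimState, valve: ValveModel, chordae: ChordaeNetwork,
            plan: ProcedurePlan, model: FEModel | None = None,
            cfg: SolverConfig | None = None) -> SimState:
    """Relocate the anterolateral papillary muscle: displace every APM
    chordal origin by ``plan.pmr_magnitude`` along the unit vector from the
    current APM tip toward the left trigone, with the annulus and all other
    origins fixed."""
    if not plan.pmr:
        raise ValueError("run_pmr called but plan.pmr is off")
    model = model or make_model(valve, chordae)
    cfg = cfg or SolverConfig()
    apm = np.nonzero(chordae.origin_pm == 0)[0]
    ppm = np.nonzero(chordae.origin_pm == 1)[0]
    tip = state.pm_tips["APM"]
    trig = state.x[valve.landmarks["left_trigone"]]
    u = trig - tip
    u = u / np.linalg.norm(u)
    gids = model.origin_ids[apm]
    stage = Stage(
        fixed=np.concatenate([valve.annulus_loop, model.origin_ids[ppm]]),
        prescribed_ids=gids,
        prescribed_targets=state.x[gids] + plan.pmr_magnitude * u,
        contact=True,
    )
    st = solve_quasistatic(model, state.x.copy(), stage, cfg)
    st.pm_tips = dict(state.pm_tips)
    _update_tips(st, state, model, chordae)
    return st


def run_closure(state: SimState, valve: ValveModel, chordae: ChordaeNetwork,
                plan: ProcedurePlan, model: FEModel | None = None,
                cfg: SolverConfig | None = None) -> SimState:
    """Close the valve: ramp the transvalvular pressure on the ventricular
    leaflet surfaces while the chordal origins follow their configured
    diastole-to-systole displacement and the annulus is held fixed."""
    model = model or make_model(valve, chordae)
    cfg = cfg or SolverConfig()
    gids = model.origin_ids
    stage = Stage(
        fixed=valve.annulus_loop.astype(np.int64),
        prescribed_ids=gids,
        prescribed_targets=state.x[gids] + chordae.systolic_delta,
        pressure=plan.closure_pressure_kpa,
        contact=True,
    )
    st = solve_quasistatic(model, state.x.copy(), stage, cfg)
    st.pm_tips = dict(state.pm_tips)
    _update_tips(st, state, model, chordae)
    return st


def run_case(valve: ValveModel, chordae: ChordaeNetwork, plan: ProcedurePlan,
             model: FEModel | None = None, cfg: SolverConfig | None = None,
             pretension: PretensionResult | None = None) -> CaseResult:
    """Run the full pipeline for one repair configuration."""
    model = model or make_model(valve, chordae)
    cfg = cfg or SolverConfig()
    pre = pretension or run_pretension(valve, chordae, model, cfg)
    post_repair = None
    post_pmr = None
    ring = None
    st = pre.state
    if plan.ring is not None:
        ring_geo = build_ring(*plan.ring)
        post_repair, ring = run_annuloplasty(valve, chordae, pre, ring_geo, model, cfg)
        st = post_repair
    if plan.pmr:
        post_pmr = run_pmr(st, valve, chordae, plan, model, cfg)
        st = post_pmr
    closed = run_closure(st, valve, chordae, plan, model, cfg)
    return CaseResult(plan=plan, pretension=pre, post_repair=post_repair,
                      post_pmr=post_pmr, closed=closed, ring=ring)
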