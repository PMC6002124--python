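"""Parametric synthetic mitral-apparatus generator.

Builds a labelled finite-element surface mesh of the two mitral leaflets on
a dilated saddle-shaped annulus, plus a branched chordae-tendineae network
with papillary-muscle (PM) tip origins, emulating a functional-mitral-
regurgitation (FMR) state: dilated annulus (area ~945 mm^2, intercommissural
~39 mm, septal-lateral ~33.5 mm), a tethered posterior leaflet whose chords
originate from 8 pre-shortened posteromedial-PM (PPM) chordal origins, and a
posterior-lateral (P1-P2) coaptation deficiency.

Model frame: origin at the annulus centroid, +z the annular least-squares
plane normal pointing atrially, +x toward the mid-anterior ("saddle horn")
landmark, +y toward the lateral (anterolateral) commissure.  Units mm.

The generated mesh is the stress-free reference configuration of the
leaflets at middle diastole; chord rest lengths are set in the diastolic
configuration in which the tethered chordal origins have been translated
toward the annular plane (so that displacing them back to their true,
dilated positions generates the tethering pretension).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .geometry import Plane, least_squares_plane, polygon_area_2d

SCALLOPS = ("A1", "A2", "A3", "P1", "P2", "P3")

__all__ = ["GeneratorParams", "ValveModel", "ChordaeNetwork", "build_valve",
           "apply_diastolic_tethering", "SCALLOPS"]


@dataclass(frozen=True)
class GeneratorParams:
    """Targets and knobs of the synthetic apparatus.

    Defaults emulate the dilated FMR patient state; ``seed`` adds small
    (<= a few %) reproducible variability to leaflet heights, tethering
    magnitudes and PM positions without touching the annulus targets.
    """

    # annulus targets (mm, mm^2)
    annular_area: float = 944.693
    intercommissural: float = 39.1
    septal_lateral: float = 33.51
    saddle_height: float = 2.0
    anterior_fraction: float = 0.40

    # leaflet material lengths annulus -> free edge (mm)
    aml_height_mid: float = 21.0
    aml_height_comm: float = 9.0
    pml_height_mid: float = 13.0
    pml_height_comm: float = 8.0
    #: posterior-lateral scallop height deficiency (mm) centred in P1,
    #: responsible for the baseline regurgitant gap
    p1_deficit: float = 4.5
    p1_deficit_center: float = 0.70 * np.pi  # annular angle of the deficit
    #: inward tilt of the leaflet descent from the annular normal (deg)
    aml_tilt_deg: float = 24.0
    pml_tilt_deg: float = 26.0
    belly_sag: float = 1.2  # ventricular belly bulge (mm)

    thickness_aml: float = 1.3
    thickness_pml: float = 1.0
    fiber_angle_aml: float = 30.0
    fiber_angle_pml: float = 40.0

    # chordal topology (per PM region: 6 marginal + 2 strut/basal origins)
    marginal_origins_per_pm: int = 6
    marginal_insertions_per_origin: int = 3
    chord_area_marginal: float = 0.4
    chord_area_strut: float = 0.9
    chord_slack: float = 0.005
    #: extra shortness of the anterolateral-PM chords relative to their
    #: nominal taut length (the dilated LV displaces the APM apically and
    #: laterally, leaving its chords tight: the "tethering near the anterior
    #: PM" component of the patient state)
    apm_chord_prestretch: float = 0.13
    strut_insertion_s: float = 0.55
    #: leaflet descent tilt from the annular normal in the nominal *closed*
    #: configuration (deg); chord rest lengths are sized so each chord goes
    #: taut when its insertion reaches this closed position while the origin
    #: sits at its systolic location — the physiological sizing of chordae.
    #: The tethered posterior leaflet closes as a much more upright curtain
    #: than the anterior leaflet (restricted PML motion in FMR).
    closed_tilt_aml_deg: float = 64.0
    closed_tilt_pml_deg: float = 64.0

    # PM tips in the dilated (true) state
    apm_tip: tuple[float, float, float] = (-8.0, 18.0, -35.0)
    ppm_tip: tuple[float, float, float] = (-10.0, -16.0, -30.0)
    pm_spread: float = 2.5  # origin scatter radius about the tip (mm)

    #: angular split of the chordal territories: the APM serves the
    #: annulus arc (0, split), the PPM serves (split, 2*pi) — the posterior
    #: PM carries the whole posterior-leaflet margin including P1
    pm_split_theta: float = 0.72 * np.pi
    #: tethering displacement magnitudes (mm) of the 8 PPM origins, graded
    #: 3-6 mm and strongest for the P1/P2-serving marginal groups; order
    #: matches the PPM origin list (6 marginal groups from P1 around to A3,
    #: then the AML strut and the P2 basal origin)
    tether_magnitudes: tuple[float, ...] = (6.0, 5.5, 4.5, 3.5, 3.0, 3.0, 3.0, 5.0)

    #: systolic chordal-origin displacement toward the annulus centroid (mm)
    systolic_origin_motion: float = 4.0

    # discretization
    n_circ: int = 64
    n_rad: int = 6

    seed: int = 0
    jitter: float = 0.02

    def __post_init__(self) -> None:
        for name in ("annular_area", "intercommissural", "septal_lateral",
                     "aml_height_mid", "pml_height_mid", "thickness_aml",
                     "thickness_pml", "chord_area_marginal", "chord_area_strut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_circ % 4 or self.n_circ < 56:
            raise ValueError("n_circ must be a multiple of 4 and >= 56")
        if self.n_rad < 4:
            raise ValueError("n_rad must be >= 4")
        if len(self.tether_magnitudes) != 8:
            raise ValueError("exactly 8 tethering magnitudes are required")
        if min(self.tether_magnitudes) <= 0:
            raise ValueError("tethering magnitudes must be > 0")


@dataclass
class ValveModel:
    """Labelled leaflet surface mesh with landmarks (see module docstring
    for the frame convention)."""

    nodes: np.ndarray            # (N, 3)
    tris: np.ndarray             # (M, 3) wound so normals point atrially
    tri_region: np.ndarray       # (M,) 0 = AML, 1 = PML
    tri_scallop: np.ndarray      # (M,) index into SCALLOPS
    thickness: np.ndarray        # (M,) membrane thickness per element
    fiber_field: np.ndarray      # (M, 2, 3) unit in-plane fiber directions
    annulus_loop: np.ndarray     # ordered closed loop of node ids
    landmarks: dict              # name -> node id on the annulus loop
    free_edge: dict              # 'AML'/'PML' -> ordered node id arrays
    midsection_patches: dict     # 'AML'/'PML' -> node id arrays
    apm_tip: np.ndarray
    ppm_tip: np.ndarray
    node_station: np.ndarray     # (N,) circumferential station index
    node_ring: np.ndarray        # (N,) radial ring index (0 = annulus)
    station_theta: np.ndarray    # (n_circ,) annular angle per station
    params: GeneratorParams | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def annulus_plane(self) -> Plane:
        return least_squares_plane(self.nodes[self.annulus_loop])

    def tri_centroids(self) -> np.ndarray:
        return self.nodes[self.tris].mean(axis=1)

    def patch_elements(self, leaflet: str) -> np.ndarray:
        """Element ids whose three nodes all lie in a midsection patch."""
        nodeset = set(int(i) for i in self.midsection_patches[leaflet])
        mask = np.array([all(int(v) in nodeset for v in t) for t in self.tris])
        return np.nonzero(mask)[0]


@dataclass
class ChordaeNetwork:
    """Branched chordae: origin points (APM/PPM tagged), internal branch
    nodes, and 2-node segments connecting origins/branches to leaflet
    insertion nodes.

    ``origins`` holds the *current* (diastolic) origin positions; for
    tethered origins this is the shortened position and
    ``origins_pre_shortening`` the true, dilated location that the
    pretension step restores.
    """

    origins: np.ndarray                 # (K, 3)
    origin_pm: np.ndarray               # (K,) 0 = APM, 1 = PPM
    origins_pre_shortening: np.ndarray  # (K, 3)
    branch_nodes: np.ndarray            # (B, 3)
    branch_parent_origin: np.ndarray    # (B,) origin id feeding the branch
    # segments: endpoint = (kind, index); kind 0 origin, 1 branch, 2 leaflet node
    seg_a: np.ndarray                   # (S, 2) [kind, index]
    seg_b: np.ndarray                   # (S, 2)
    slack_length: np.ndarray            # (S,) rest length (mm)
    area: np.ndarray                    # (S,) cross-section (mm^2)
    seg_type: np.ndarray                # (S,) 0 marginal, 1 strut/basal
    tethered_origin_ids: np.ndarray     # (8,)
    shortening: np.ndarray              # (8,) magnitudes (mm)
    systolic_delta: np.ndarray          # (K, 3) diastole->systole origin motion

    @property
    def n_origins(self) -> int:
        return len(self.origins)

    def origin_segments(self, origin_id: int) -> np.ndarray:
        """Segment ids emanating from an origin (directly)."""
        return np.nonzero((self.seg_a[:, 0] == 0) & (self.seg_a[:, 1] == origin_id))[0]


# ----------------------------------------------------------------- annulus

def _annulus_xy(theta: np.ndarray, p: GeneratorParams, q: float) -> np.ndarray:
    a_ant = p.anterior_fraction * p.septal_lateral
    a_post = p.septal_lateral - a_ant
    b = p.intercommissural / 2.0
    c = np.cos(theta)
    x = np.where(c >= 0, a_ant * np.abs(c) ** q, -a_post * np.abs(c) ** q)
    return np.stack([x, b * np.sin(theta)], axis=-1)


def _solve_annulus_exponent(p: GeneratorParams) -> float:
    theta = 2 * np.pi * np.arange(1024) / 1024

    def err(q: float) -> float:
        return polygon_area_2d(_annulus_xy(theta, p, q)) - p.annular_area

    lo, hi = err(0.2), err(6.0)
    if lo * hi > 0:
        raise ValueError(
            "annulus targets are infeasible: no D-shape with the requested "
            "intercommissural/septal-lateral spans encloses the target area"
        )
    return brentq(err, 0.2, 6.0, xtol=1e-12)


# ------------------------------------------------------------------ leaflets

def _leaflet_height(theta: np.ndarray, p: GeneratorParams, rng_scale: np.ndarray) -> np.ndarray:
    """Material length annulus -> free edge per station angle."""
    c = np.cos(theta)
    anterior = c > 0
    h = np.where(
        anterior,
        p.aml_height_comm + (p.aml_height_mid - p.aml_height_comm) * np.abs(c) ** 0.7,
        p.pml_height_comm + (p.pml_height_mid - p.pml_height_comm) * np.abs(c) ** 0.7,
    )
    th = np.mod(theta, 2 * np.pi)
    deficit = p.p1_deficit * np.exp(-0.5 * ((th - p.p1_deficit_center) / 0.45) ** 2)
    h = h - np.where(anterior, 0.0, deficit)
    h = h * rng_scale
    if np.any(h <= 1.0):
        raise ValueError(
            "infeasible leaflet heights: the posterior deficit leaves a "
            "leaflet height <= 1 mm; reduce p1_deficit or raise pml heights"
        )
    return h


def _scallop_of(theta: float) -> int:
    th = np.mod(theta, 2 * np.pi)
    if th < np.pi / 6 or th >= 11 * np.pi / 6:
        return 1  # A2
    if th < np.pi / 2:
        return 0  # A1 (lateral)
    if th < 5 * np.pi / 6:
        return 3  # P1
    if th < 7 * np.pi / 6:
        return 4  # P2
    if th < 3 * np.pi / 2:
        return 5  # P3
    if th < 11 * np.pi / 6:
        return 2  # A3 (septal)
    return 1


def build_valve(params: GeneratorParams | None = None) -> tuple[ValveModel, ChordaeNetwork]:
    """Generate the synthetic mitral apparatus.

    Returns the leaflet model and the chordae network *in the diastolic
    configuration*: tethered PPM origins are already shortened toward the
    annular plane (see :func:`apply_diastolic_tethering`) and chord rest
    lengths are set there, so the pretension step that displaces them back
    to ``origins_pre_shortening`` generates the tethering tension.

    Deterministic: identical params (including seed) give bit-identical
    geometry.
    """
    p = params if params is not None else GeneratorParams()
    rng = np.random.default_rng(p.seed)
    n, m = p.n_circ, p.n_rad

    theta = 2 * np.pi * np.arange(n) / n
    q_ann = _solve_annulus_exponent(p)
    axy = _annulus_xy(theta, p, q_ann)
    az = 0.5 * p.saddle_height * np.cos(2 * theta)
    annulus = np.column_stack([axy, az])

    jit = 1.0 + p.jitter * rng.uniform(-1.0, 1.0, size=n)
    # smooth the station jitter so neighbouring heights stay coherent
    k = np.exp(-0.5 * (np.arange(-4, 5) / 1.5) ** 2)
    k /= k.sum()
    jit = 1.0 + np.convolve(np.r_[jit[-4:], jit, jit[:4]] - 1.0, k, mode="same")[4:-4]
    heights = _leaflet_height(theta, p, jit)

    tilt = np.where(np.cos(theta) > 0, np.radians(p.aml_tilt_deg), np.radians(p.pml_tilt_deg))
    r_in = -axy / np.linalg.norm(axy, axis=1, keepdims=True)  # inward, in-plane

    s = np.arange(m + 1) / m
    nodes = np.empty(((m + 1) * n, 3))
    for i, si in enumerate(s):
        step = heights * si
        xy = axy + step[:, None] * np.sin(tilt)[:, None] * r_in
        z = az - step * np.cos(tilt) - p.belly_sag * np.sin(np.pi * si)
        nodes[i * n:(i + 1) * n] = np.column_stack([xy, z])

    node_station = np.tile(np.arange(n), m + 1)
    node_ring = np.repeat(np.arange(m + 1), n)

    tris = []
    tri_station = []
    for i in range(m):
        for j in range(n):
            jp = (j + 1) % n
            p00 = i * n + j
            p10 = i * n + jp
            p01 = (i + 1) * n + j
            p11 = (i + 1) * n + jp
            tris.append((p00, p10, p11))
            tris.append((p00, p11, p01))
            tri_station += [j, j]
    tris = np.asarray(tris, dtype=np.int64)
    tri_station = np.asarray(tri_station)

    cent = nodes[tris].mean(axis=1)
    th_c = np.mod(np.arctan2(cent[:, 1], cent[:, 0]), 2 * np.pi)
    tri_region = ((th_c > np.pi / 2) & (th_c < 3 * np.pi / 2)).astype(np.int64)
    tri_scallop = np.array([_scallop_of(t) for t in th_c], dtype=np.int64)

    # orient windings so element normals point atrially (inward + up)
    e1 = nodes[tris[:, 1]] - nodes[tris[:, 0]]
    e2 = nodes[tris[:, 2]] - nodes[tris[:, 0]]
    nrm = np.cross(e1, e2)
    ref = np.column_stack([-cent[:, 0], -cent[:, 1], np.full(len(cent), 12.0)])
    flip = np.einsum("ij,ij->i", nrm, ref) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    thickness = np.where(tri_region == 0, p.thickness_aml, p.thickness_pml)

    # fibers: +-theta_f about the element normal, from the circumferential axis
    e1 = nodes[tris[:, 1]] - nodes[tris[:, 0]]
    e2 = nodes[tris[:, 2]] - nodes[tris[:, 0]]
    nrm = np.cross(e1, e2)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    circ = np.column_stack([-np.sin(th_c), np.cos(th_c), np.zeros(len(th_c))])
    circ -= np.einsum("ij,ij->i", circ, nrm)[:, None] * nrm
    circ /= np.linalg.norm(circ, axis=1, keepdims=True)
    perp = np.cross(nrm, circ)
    ang = np.radians(np.where(tri_region == 0, p.fiber_angle_aml, p.fiber_angle_pml))
    fibers = np.stack(
        [
            np.cos(ang)[:, None] * circ + np.sin(ang)[:, None] * perp,
            np.cos(ang)[:, None] * circ - np.sin(ang)[:, None] * perp,
        ],
        axis=1,
    )

    lat, sep = n // 4, 3 * n // 4
    landmarks = {
        "saddle_horn": 0,
        "lateral_commissure": lat,
        "mid_posterior": n // 2,
        "septal_commissure": sep,
        "left_trigone": int(round(0.40 * np.pi / (2 * np.pi) * n)),
        "right_trigone": n - int(round(0.40 * np.pi / (2 * np.pi) * n)),
    }

    fe_row = m * n
    aml_cols = [j for j in range(n) if np.cos(theta[j]) > 1e-9]
    aml_cols = sorted(aml_cols, key=lambda j: np.mod(theta[j] + np.pi, 2 * np.pi))  # A3 -> A1
    pml_cols = [j for j in range(n) if np.cos(theta[j]) < -1e-9]
    pml_cols = sorted(pml_cols, key=lambda j: theta[j])  # P1 -> P3
    free_edge = {
        "AML": np.array([fe_row + j for j in aml_cols], dtype=np.int64),
        "PML": np.array([fe_row + j for j in pml_cols], dtype=np.int64),
    }

    # midsection patches: nodes within a square (circ x radial material
    # coordinates) centred mid-belly at A2 / P2
    def _patch(center_theta: float, half: float) -> np.ndarray:
        dth = np.mod(theta[node_station] - center_theta + np.pi, 2 * np.pi) - np.pi
        radius = np.linalg.norm(nodes[:, :2], axis=1)
        circ_dist = dth * radius
        h_here = heights[node_station]
        radial = (node_ring / m) * h_here
        target = 0.5 * heights[int(round(center_theta / (2 * np.pi) * n)) % n]
        inside = (np.abs(circ_dist) <= half) & (np.abs(radial - target) <= half)
        inside &= (node_ring > 0) & (node_ring < m)
        return np.nonzero(inside)[0]

    patches = {"AML": _patch(0.0, 5.0), "PML": _patch(np.pi, 4.5)}

    valve = ValveModel(
        nodes=nodes,
        tris=tris,
        tri_region=tri_region,
        tri_scallop=tri_scallop,
        thickness=thickness,
        fiber_field=fibers,
        annulus_loop=np.arange(n, dtype=np.int64),
        landmarks=landmarks,
        free_edge=free_edge,
        midsection_patches=patches,
        apm_tip=np.asarray(p.apm_tip, dtype=float) + 0.5 * rng.normal(size=3) * (p.jitter > 0),
        ppm_tip=np.asarray(p.ppm_tip, dtype=float) + 0.5 * rng.normal(size=3) * (p.jitter > 0),
        node_station=node_station,
        node_ring=node_ring,
        station_theta=theta,
        params=p,
    )

    chordae = _build_chordae(valve, p, rng)
    chordae = apply_diastolic_tethering(valve, chordae)
    return valve, chordae


# ------------------------------------------------------------------ chordae

def _build_chordae(valve: ValveModel, p: GeneratorParams, rng: np.random.Generator) -> ChordaeNetwork:
    n = p.n_circ
    theta = valve.station_theta
    nodes = valve.nodes

    origins: list[np.ndarray] = []
    origin_pm: list[int] = []
    branch_nodes: list[np.ndarray] = []
    branch_parent: list[int] = []
    seg_a: list[tuple[int, int]] = []
    seg_b: list[tuple[int, int]] = []
    areas: list[float] = []
    seg_type: list[int] = []

    served_edges = {}  # pm -> ordered free-edge node ids it serves
    for pm, tip in ((0, valve.apm_tip), (1, valve.ppm_tip)):
        # APM (pm=0, +y side) serves theta in (0, split); PPM serves the
        # rest, including the whole posterior-lateral margin
        lo, hi = (0.0, p.pm_split_theta) if pm == 0 else (p.pm_split_theta, 2 * np.pi)
        cols = [j for j in range(n) if lo + 1e-9 < theta[j] < hi - 1e-9]
        cols.sort(key=lambda j: theta[j])
        fe = [p.n_rad * n + j for j in cols]
        served_edges[pm] = fe

    for pm, tip in ((0, valve.apm_tip), (1, valve.ppm_tip)):
        fe = served_edges[pm]
        groups = np.array_split(np.asarray(fe), p.marginal_origins_per_pm)
        for gi, grp in enumerate(groups):
            oid = len(origins)
            offset = rng.normal(size=3)
            offset *= p.pm_spread / max(np.linalg.norm(offset), 1e-9)
            origins.append(np.asarray(tip, dtype=float) + offset)
            origin_pm.append(pm)
            take = np.linspace(0, len(grp) - 1, p.marginal_insertions_per_origin)
            ins = grp[np.round(take).astype(int)]
            centroid = nodes[ins].mean(axis=0)
            bid = len(branch_nodes)
            branch_nodes.append(origins[oid] + 0.65 * (centroid - origins[oid]))
            branch_parent.append(oid)
            seg_a.append((0, oid))
            seg_b.append((1, bid))
            areas.append(p.chord_area_marginal * len(ins))
            seg_type.append(0)
            for nid in ins:
                seg_a.append((1, bid))
                seg_b.append((2, int(nid)))
                areas.append(p.chord_area_marginal)
                seg_type.append(0)

        # strut (AML belly) and basal (PML belly) origins
        sgn = 1.0 if pm == 0 else -1.0
        for region, th_t in (("AML", sgn * 0.28 * np.pi), ("PML", np.pi - sgn * 0.15 * np.pi)):
            oid = len(origins)
            offset = rng.normal(size=3)
            offset *= p.pm_spread / max(np.linalg.norm(offset), 1e-9)
            origins.append(np.asarray(tip, dtype=float) + offset)
            origin_pm.append(pm)
            ring = int(round(p.strut_insertion_s * p.n_rad))
            jc = int(round(np.mod(th_t, 2 * np.pi) / (2 * np.pi) * n)) % n
            for j in (jc - 1, jc + 1):
                nid = ring * n + (j % n)
                seg_a.append((0, oid))
                seg_b.append((2, nid))
                areas.append(p.chord_area_strut)
                seg_type.append(1)

    origins_arr = np.asarray(origins)
    origin_pm_arr = np.asarray(origin_pm, dtype=np.int64)
    tethered = np.nonzero(origin_pm_arr == 1)[0]
    if len(tethered) != 8:
        raise ValueError("default chordal topology must yield exactly 8 PPM origins")

    jit = 1.0 + p.jitter * 2.0 * rng.uniform(-1.0, 1.0, size=8)
    shortening = np.asarray(p.tether_magnitudes, dtype=float) * jit

    centroid = nodes[valve.annulus_loop].mean(axis=0)
    sys_dir = centroid[None, :] - origins_arr
    sys_dir /= np.linalg.norm(sys_dir, axis=1, keepdims=True)
    systolic_delta = p.systolic_origin_motion * sys_dir

    seg_a_arr = np.asarray(seg_a, dtype=np.int64)
    seg_b_arr = np.asarray(seg_b, dtype=np.int64)
    net = ChordaeNetwork(
        origins=origins_arr.copy(),
        origin_pm=origin_pm_arr,
        origins_pre_shortening=origins_arr.copy(),
        branch_nodes=np.asarray(branch_nodes),
        branch_parent_origin=np.asarray(branch_parent, dtype=np.int64),
        seg_a=seg_a_arr,
        seg_b=seg_b_arr,
        slack_length=np.ones(len(seg_a_arr)),  # provisional, set below
        area=np.asarray(areas),
        seg_type=np.asarray(seg_type, dtype=np.int64),
        tethered_origin_ids=tethered,
        shortening=shortening,
        systolic_delta=systolic_delta,
    )
    # Chord sizing: rest lengths are proportioned at the diastolic geometry
    # but scaled per origin so the chord tree goes taut exactly when its
    # insertions reach the nominal *closed* leaflet position while the
    # origin sits at its systolic location (chordae are sized to carry the
    # closed valve).  APM chords are additionally shortened by the
    # prestretch factor (anterior-PM tethering of the dilated ventricle).
    net.slack_length = _segment_lengths(valve, net) * (1.0 + p.chord_slack)
    closed = _closed_leaflet_target(valve, p)
    for oid in range(len(origins_arr)):
        ins = _origin_insertions(net, oid)
        if len(ins) == 0:
            continue
        d_dia = float(np.mean(np.linalg.norm(nodes[ins] - origins_arr[oid], axis=1)))
        o_sys = origins_arr[oid] + systolic_delta[oid]
        d_tgt = float(np.mean(np.linalg.norm(closed[ins] - o_sys, axis=1)))
        factor = d_tgt / max(d_dia, 1e-9)
        if origin_pm_arr[oid] == 0:
            factor /= 1.0 + p.apm_chord_prestretch
        else:
            # tethered (PPM) chords are at most just-taut at the shortened
            # diastolic state, so restoring each origin by its shortening
            # magnitude always generates a strictly positive tethering
            # tension (the defining property of the tethered configuration)
            factor = min(factor, 1.0)
        net.slack_length[_origin_tree_segments(net, oid)] *= factor
    return net


def _closed_leaflet_target(valve: ValveModel, p: GeneratorParams) -> np.ndarray:
    """Nominal closed-configuration position of every leaflet node: its
    annulus station point descended by its radial material length at the
    closed tilt angle."""
    theta = valve.station_theta
    j = valve.node_station
    ann = valve.nodes[valve.annulus_loop][j]
    axy = ann[:, :2]
    r_in = -axy / np.linalg.norm(axy, axis=1, keepdims=True)
    # radial material length from the annulus to this node
    edge_xy = valve.nodes[:, :2]
    h_here = np.linalg.norm(valve.nodes - ann, axis=1)
    del edge_xy
    anterior = np.cos(theta[j]) > 0
    tilt = np.where(anterior, np.radians(p.closed_tilt_aml_deg),
                    np.radians(p.closed_tilt_pml_deg))
    out = ann.copy()
    out[:, :2] += (h_here * np.sin(tilt))[:, None] * r_in
    out[:, 2] -= h_here * np.cos(tilt)
    return out


def _origin_insertions(net: ChordaeNetwork, oid: int) -> np.ndarray:
    """Leaflet insertion node ids reachable from one origin."""
    ins = []
    bids = set(np.nonzero(net.branch_parent_origin == oid)[0].tolist())
    for a, b in zip(net.seg_a, net.seg_b):
        from_o = (a[0] == 0 and a[1] == oid) or (a[0] == 1 and a[1] in bids)
        if from_o and b[0] == 2:
            ins.append(int(b[1]))
    return np.asarray(ins, dtype=np.int64)


def _origin_tree_segments(net: ChordaeNetwork, oid: int) -> np.ndarray:
    bids = set(np.nonzero(net.branch_parent_origin == oid)[0].tolist())
    segs = [
        k for k, a in enumerate(net.seg_a)
        if (a[0] == 0 and a[1] == oid) or (a[0] == 1 and a[1] in bids)
    ]
    return np.asarray(segs, dtype=np.int64)


def _endpoint_positions(valve: ValveModel, net: ChordaeNetwork, ends: np.ndarray) -> np.ndarray:
    pos = np.empty((len(ends), 3))
    for kind, source in ((0, net.origins), (1, net.branch_nodes), (2, valve.nodes)):
        mask = ends[:, 0] == kind
        pos[mask] = source[ends[mask, 1]]
    return pos


def _segment_lengths(valve: ValveModel, net: ChordaeNetwork) -> np.ndarray:
    pa = _endpoint_positions(valve, net, net.seg_a)
    pb = _endpoint_positions(valve, net, net.seg_b)
    return np.linalg.norm(pb - pa, axis=1)


def chord_axes(valve: ValveModel, net: ChordaeNetwork) -> np.ndarray:
    """Unit mean chord axis per origin (from the origin toward its
    insertions / branch targets)."""
    axes = np.zeros((net.n_origins, 3))
    pb = _endpoint_positions(valve, net, net.seg_b)
    for oid in range(net.n_origins):
        segs = net.origin_segments(oid)
        d = pb[segs].mean(axis=0) - net.origins[oid]
        axes[oid] = d / np.linalg.norm(d)
    return axes


def apply_diastolic_tethering(valve: ValveModel, chordae: ChordaeNetwork) -> ChordaeNetwork:
    """Shorten the tethered chords: translate each tethered origin by its
    shortening magnitude along its mean chord axis toward the annular
    least-squares plane, carrying its branch nodes along, and reset the rest
    lengths of the affected segments at the shortened configuration.

    Untethered origins are untouched.  Raises if a shortening magnitude
    exceeds the origin's distance to the annular plane.
    """
    plane = valve.annulus_plane()
    axes = chord_axes(valve, chordae)
    origins = chordae.origins_pre_shortening.copy()
    branches = chordae.branch_nodes.copy()
    slack_scale = chordae.slack_length / np.maximum(_segment_lengths(valve, chordae), 1e-12)

    for k, oid in enumerate(chordae.tethered_origin_ids):
        d_plane = abs(plane.signed_distance(origins[oid]))
        mag = chordae.shortening[k]
        if mag >= d_plane:
            raise ValueError(
                f"shortening {mag:.2f} mm of origin {oid} exceeds its distance "
                f"{d_plane:.2f} mm to the annular plane"
            )
        axis = axes[oid]
        if plane.signed_distance(origins[oid] + axis) < plane.signed_distance(origins[oid]) - 1e-12:
            axis = -axis  # ensure motion is toward the plane
        delta = mag * axis
        origins[oid] = origins[oid] + delta
        # branch nodes move by the distal fraction of the chord path so the
        # shortening (and hence the pretension stretch) distributes uniformly
        # along parent and child segments
        for bid in np.nonzero(chordae.branch_parent_origin == oid)[0]:
            l_p = np.linalg.norm(chordae.branch_nodes[bid] - chordae.origins_pre_shortening[oid])
            child = np.nonzero((chordae.seg_a[:, 0] == 1) & (chordae.seg_a[:, 1] == bid))[0]
            pb = _endpoint_positions(valve, chordae, chordae.seg_b[child])
            l_c = float(np.linalg.norm(pb - chordae.branch_nodes[bid], axis=1).mean())
            branches[bid] += delta * (l_c / max(l_p + l_c, 1e-9))

    out = replace(
        chordae,
        origins=origins,
        branch_nodes=branches,
        origins_pre_shortening=chordae.origins_pre_shortening.copy(),
    )
    out.slack_length = _segment_lengths(valve, out) * slack_scale
    return out
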