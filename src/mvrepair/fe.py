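"""Quasi-static nonlinear membrane/cable solver.

Discretization
--------------
* Leaflets: constant-strain triangular membrane elements carrying the
  incompressible plane-stress Holzapfel response (:mod:`mvrepair.materials`)
  integrated over reference area x thickness.  Membranes have no bending
  stiffness.
* Chordae: two-node cable elements with the tension-only Ogden law.
* Pressure: follower load on the ventricular leaflet surface; per face
  ``f = p * (current vector area)`` distributed equally to its three nodes
  (stored winding gives the atrial normal, along which the ventricular
  pressure pushes).
* Contact: node-to-triangle penalty acting on both directed sides of a pair
  within a shell of half the summed thicknesses; "rough" mode adds an
  elastic tangential anchor set when a pair activates, "frictionless" mode
  omits it.  No attraction when separation is allowed.

Equilibrium is found by explicit central-difference pseudo-time integration
with per-node mass scaling (masses follow a tangent-stiffness bound, so the
unit time step is always stable) and kinetic damping: velocities are zeroed
whenever the kinetic energy peaks.  Convergence is declared when the RMS
residual force on free nodes falls below ``tol_rel`` times the RMS force
throughput (the sum of absolute force contributions per node), so the
criterion is scale-invariant.  The integration is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .materials import (
    HGOParams,
    OgdenParams,
    membrane_response,
    ogden_fiber_tension,
    ogden_tangent_stiffness,
)
from . import fe_kernels

#: set False to force the pure-numpy force path (used by the agreement test)
USE_KERNELS = fe_kernels.HAVE_NUMBA

__all__ = [
    "SolverConfig",
    "FEModel",
    "Stage",
    "SimState",
    "ConvergenceError",
    "solve_quasistatic",
    "internal_forces",
    "pressure_forces",
    "total_elastic_energy",
]


class ConvergenceError(RuntimeError):
    """Raised in strict mode when dynamic relaxation fails to settle."""

    def __init__(self, msg: str, history: list):
        super().__init__(msg)
        self.history = history


@dataclass
class SolverConfig:
    """Dynamic-relaxation and contact settings (units mm/kPa/mN/ms)."""

    dt: float = 1.0
    ramp_steps: int = 1600
    max_steps: int = 24000
    check_every: int = 25
    mass_update: int = 250
    tol_rel: float = 0.008       # residual rms / force-throughput rms
    balance_tol: float = 0.008   # |sum f_free| / |net applied force| (pressure stages)
    floor_force: float = 0.02    # absolute residual floor (mN)
    penalty: float = 800.0       # contact normal penalty (kPa/mm)
    friction: str = "rough"      # 'rough' | 'frictionless'
    kt_ratio: float = 0.5        # tangential/normal penalty ratio in rough mode
    contact_margin: float = 1.0  # broadphase margin (mm)
    #: fraction of the shell over which the penalty force is quadratically
    #: regularized at activation (removes the force-law kink that otherwise
    #: sustains boundary limit cycles under kinetic damping)
    contact_smooth: float = 0.15
    broadphase_every: int = 15
    vmax: float = 0.08           # velocity cap (mm per step)
    viscous: float = 0.01        # per-step viscous velocity decay
    mass_safety: float = 1.35
    strict: bool = False         # raise ConvergenceError instead of warning

    def __post_init__(self) -> None:
        if self.penalty <= 0:
            raise ValueError("contact penalty must be > 0")
        if self.friction not in ("rough", "frictionless"):
            raise ValueError("friction must be 'rough' or 'frictionless'")


@dataclass
class ContactPair:
    """One physical contact interface, resolved from both directed sides."""

    nodes_a: np.ndarray
    tris_a: np.ndarray   # triangle ids (rows into model.tris) of side a
    nodes_b: np.ndarray
    tris_b: np.ndarray
    shell: float         # contact activation distance (mm)
    separable: bool = True


@dataclass
class Stage:
    """Boundary conditions and loading of one procedure step."""

    fixed: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    prescribed_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    prescribed_targets: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    point_loads: np.ndarray | None = None  # (n_nodes, 3) constant dead loads
    pressure: float = 0.0                  # kPa on the ventricular surface
    contact: bool = True
    # elastic anchors: linear springs pulling anchor_ids toward anchor_ref
    # (used to emulate the compliance of structures outside the model, e.g.
    # the ventricular wall behind released chordal origins)
    anchor_ids: np.ndarray | None = None
    anchor_ref: np.ndarray | None = None
    anchor_k: float = 0.0

    def constrained(self) -> np.ndarray:
        return np.unique(np.concatenate([self.fixed, self.prescribed_ids]))


@dataclass
class SimState:
    """Converged nodal kinematics plus derived element/contact quantities."""

    x: np.ndarray
    v: np.ndarray
    reactions: np.ndarray            # (n_nodes, 3), nonzero on constrained nodes
    constrained: np.ndarray
    cable_stretch: np.ndarray
    cable_tension: np.ndarray        # (S,) mN, >= 0
    contact_force: np.ndarray        # (n_nodes, 3) accumulated contact force
    tri_stress_max: np.ndarray       # (M,) max principal Cauchy stress (kPa)
    tri_strain_max: np.ndarray       # (M,) max principal Green strain
    tri_F: np.ndarray                # (M, 3, 2) membrane deformation gradients
    residual: float
    residual_rel: float
    converged: bool
    steps: int
    history: list = field(default_factory=list)
    pm_tips: dict = field(default_factory=dict)
    applied_pressure: float = 0.0

    def copy_shallow(self) -> "SimState":
        import copy

        return copy.copy(self)


# ================================================================== model

class FEModel:
    """Assembled membrane + cable model of one valve/chordae pair."""

    def __init__(self, valve, chordae, materials: dict):
        self.valve = valve
        self.chordae = chordae
        self.mat_anterior: HGOParams = materials["anterior"]
        self.mat_posterior: HGOParams = materials["posterior"]
        self.mat_chordae: OgdenParams = materials["chordae"]

        nv = len(valve.nodes)
        ko = len(chordae.origins)
        self.n_leaflet = nv
        self.origin_ids = nv + np.arange(ko)
        self.branch_ids = nv + ko + np.arange(len(chordae.branch_nodes))
        self.X0 = np.vstack([valve.nodes, chordae.origins, chordae.branch_nodes])
        self.n_nodes = len(self.X0)

        self.tris = valve.tris
        self._precompute_membrane()
        self._build_cables()
        self._build_contact_pairs()
        self.pressure_faces = np.arange(len(self.tris))
        self.trib_area = self._tributary_areas()

    # -- membrane precompute -------------------------------------------------
    def _precompute_membrane(self) -> None:
        v = self.valve
        x = self.X0
        t = self.tris
        p0, p1, p2 = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
        d1, d2 = p1 - p0, p2 - p0
        n = np.cross(d1, d2)
        a2 = np.linalg.norm(n, axis=1)
        if np.any(a2 <= 1e-12):
            raise ValueError("degenerate reference triangle in leaflet mesh")
        self.A0 = 0.5 * a2
        nhat = n / a2[:, None]
        e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
        e2 = np.cross(nhat, e1)
        Dm = np.empty((len(t), 2, 2))
        Dm[:, 0, 0] = np.einsum("ij,ij->i", d1, e1)
        Dm[:, 1, 0] = 0.0
        Dm[:, 0, 1] = np.einsum("ij,ij->i", d2, e1)
        Dm[:, 1, 1] = np.einsum("ij,ij->i", d2, e2)
        det = Dm[:, 0, 0] * Dm[:, 1, 1]
        self.Bm = np.empty_like(Dm)
        self.Bm[:, 0, 0] = Dm[:, 1, 1] / det
        self.Bm[:, 1, 1] = Dm[:, 0, 0] / det
        self.Bm[:, 0, 1] = -Dm[:, 0, 1] / det
        self.Bm[:, 1, 0] = 0.0

        f3 = v.fiber_field
        self.fibers2d = np.stack(
            [
                np.stack([np.einsum("ij,ij->i", f3[:, k, :], e1),
                          np.einsum("ij,ij->i", f3[:, k, :], e2)], axis=-1)
                for k in (0, 1)
            ],
            axis=1,
        )
        self.fibers2d /= np.linalg.norm(self.fibers2d, axis=-1, keepdims=True)

        self.thickness = v.thickness.astype(float)
        reg = v.tri_region
        self.matC10 = np.where(reg == 0, self.mat_anterior.C10, self.mat_posterior.C10)
        self.matC01 = np.where(reg == 0, self.mat_anterior.C01, self.mat_posterior.C01)
        self.matk1 = np.where(reg == 0, self.mat_anterior.k1, self.mat_posterior.k1)
        self.matk2 = np.where(reg == 0, self.mat_anterior.k2, self.mat_posterior.k2)
        self.matkappa = np.where(reg == 0, self.mat_anterior.kappa, self.mat_posterior.kappa)

    def _build_cables(self) -> None:
        ch = self.chordae

        def gid(end):
            kind, idx = end
            if kind == 0:
                return self.origin_ids[idx]
            if kind == 1:
                return self.branch_ids[idx]
            return idx

        self.cables = np.array(
            [[gid(a), gid(b)] for a, b in zip(ch.seg_a, ch.seg_b)], dtype=np.int64
        )
        self.cable_L0 = ch.slack_length.astype(float)
        self.cable_area = ch.area.astype(float)

    def _tributary_areas(self) -> np.ndarray:
        trib = np.zeros(self.n_nodes)
        np.add.at(trib, self.tris.ravel(), np.repeat(self.A0 / 3.0, 3))
        return trib

    def _build_contact_pairs(self) -> None:
        v = self.valve
        aml_t = np.nonzero(v.tri_region == 0)[0]
        pml_t = np.nonzero(v.tri_region == 1)[0]
        aml_n = np.unique(self.tris[aml_t].ravel())
        pml_n = np.unique(self.tris[pml_t].ravel())
        t_a = v.thickness[v.tri_region == 0]
        t_p = v.thickness[v.tri_region == 1]
        shell = 0.5 * (
            (float(t_a.mean()) if len(t_a) else 1.0)
            + (float(t_p.mean()) if len(t_p) else 1.0)
        )
        self.leaflet_pair = ContactPair(aml_n, aml_t, pml_n, pml_t, shell)
        # adjacency for self-exclusion near the commissures (shared nodes)
        nbr = [set() for _ in range(self.n_nodes)]
        for a, b, c in self.tris:
            nbr[a].update((a, b, c))
            nbr[b].update((a, b, c))
            nbr[c].update((a, b, c))
        self.node_neighbors = nbr

    # -- force contributions --------------------------------------------------
    def membrane_forces(self, x: np.ndarray, out: np.ndarray,
                        throughput: np.ndarray | None = None,
                        collect: dict | None = None) -> None:
        if USE_KERNELS:
            m = len(self.tris)
            want_c = collect is not None
            thr = throughput if throughput is not None else np.empty(0)
            C2 = np.empty((m, 2, 2)) if want_c else np.empty((0, 2, 2))
            F = np.empty((m, 3, 2)) if want_c else np.empty((0, 3, 2))
            S2 = np.empty((m, 2, 2)) if want_c else np.empty((0, 2, 2))
            lam3 = np.empty(m) if want_c else np.empty(0)
            stiff = np.empty(m)
            fe_kernels.membrane_forces_kernel(
                x, self.tris, self.Bm, self.fibers2d,
                self.matC10, self.matC01, self.matk1, self.matk2, self.matkappa,
                self.thickness, self.A0, out, thr, throughput is not None,
                C2, F, S2, lam3, stiff, want_c,
            )
            if want_c:
                collect.update(F=F, C2=C2, lam3=lam3, S2=S2, stiff=stiff)
            return
        t = self.tris
        d1 = x[t[:, 1]] - x[t[:, 0]]
        d2 = x[t[:, 2]] - x[t[:, 0]]
        area2 = np.linalg.norm(np.cross(d1, d2), axis=1)
        bad = area2 < 1e-10
        if np.any(bad):
            raise RuntimeError(f"collapsed membrane element(s): {np.nonzero(bad)[0][:5]}")
        Ds = np.stack([d1, d2], axis=-1)           # (m,3,2)
        F = Ds @ self.Bm                            # (m,3,2)
        C2 = np.einsum("mia,mib->mab", F, F)
        S2, lam3, stiff = membrane_response(
            C2, self.fibers2d, self.matC10, self.matC01,
            self.matk1, self.matk2, self.matkappa,
        )
        P = F @ S2                                  # (m,3,2)
        H = (self.A0 * self.thickness)[:, None, None] * (P @ np.swapaxes(self.Bm, 1, 2))
        f1 = -H[:, :, 0]
        f2 = -H[:, :, 1]
        f0 = -(f1 + f2)
        np.add.at(out, t[:, 0], f0)
        np.add.at(out, t[:, 1], f1)
        np.add.at(out, t[:, 2], f2)
        if throughput is not None:
            g = np.linalg.norm(H, axis=1).sum(axis=1)
            np.add.at(throughput, t.ravel(), np.repeat(g, 3))
        if collect is not None:
            collect["F"] = F
            collect["C2"] = C2
            collect["lam3"] = lam3
            collect["S2"] = S2
            collect["stiff"] = stiff

    def membrane_stiffness(self, x: np.ndarray) -> np.ndarray:
        """Per-node tangent-stiffness bound of the membrane part (mN/mm)."""
        t = self.tris
        if USE_KERNELS:
            stiff = np.empty(len(t))
            fe_kernels.membrane_forces_kernel(
                x, t, self.Bm, self.fibers2d,
                self.matC10, self.matC01, self.matk1, self.matk2, self.matkappa,
                self.thickness, self.A0, np.zeros_like(x), np.empty(0), False,
                np.empty((0, 2, 2)), np.empty((0, 3, 2)), np.empty((0, 2, 2)),
                np.empty(0), stiff, False,
            )
        else:
            d1 = x[t[:, 1]] - x[t[:, 0]]
            d2 = x[t[:, 2]] - x[t[:, 0]]
            Ds = np.stack([d1, d2], axis=-1)
            F = Ds @ self.Bm
            C2 = np.einsum("mia,mib->mab", F, F)
            _, _, stiff = membrane_response(
                C2, self.fibers2d, self.matC10, self.matC01,
                self.matk1, self.matk2, self.matkappa,
            )
        bnorm = np.einsum("mab,mab->m", self.Bm, self.Bm)
        k_e = stiff * self.thickness * self.A0 * bnorm * 2.0
        k = np.zeros(self.n_nodes)
        np.add.at(k, t.ravel(), np.repeat(k_e, 3))
        return k

    def cable_forces(self, x: np.ndarray, out: np.ndarray,
                     throughput: np.ndarray | None = None,
                     collect: dict | None = None) -> None:
        if len(self.cables) == 0:
            return
        if USE_KERNELS:
            thr = throughput if throughput is not None else np.empty(0)
            lam = np.empty(len(self.cables))
            T = np.empty(len(self.cables))
            mus = np.array([t[0] for t in self.mat_chordae.terms])
            alphas = np.array([t[1] for t in self.mat_chordae.terms])
            fe_kernels.cable_forces_kernel(
                x, self.cables, self.cable_L0, self.cable_area, mus, alphas,
                out, thr, throughput is not None, lam, T,
            )
            if collect is not None:
                collect["cable_stretch"] = lam
                collect["cable_tension"] = T
            return
        a, b = self.cables[:, 0], self.cables[:, 1]
        d = x[b] - x[a]
        L = np.linalg.norm(d, axis=1)
        lam = L / self.cable_L0
        T = ogden_fiber_tension(np.maximum(lam, 1e-9), self.mat_chordae, self.cable_area)
        u = d / np.maximum(L, 1e-12)[:, None]
        fa = T[:, None] * u
        np.add.at(out, a, fa)
        np.add.at(out, b, -fa)
        if throughput is not None:
            np.add.at(throughput, a, T)
            np.add.at(throughput, b, T)
        if collect is not None:
            collect["cable_stretch"] = lam
            collect["cable_tension"] = T

    def cable_stiffness(self, x: np.ndarray) -> np.ndarray:
        k = np.zeros(self.n_nodes)
        if len(self.cables) == 0:
            return k
        a, b = self.cables[:, 0], self.cables[:, 1]
        L = np.linalg.norm(x[b] - x[a], axis=1)
        lam = L / self.cable_L0
        kc = ogden_tangent_stiffness(lam, self.mat_chordae, self.cable_area, self.cable_L0)
        np.add.at(k, a, kc)
        np.add.at(k, b, kc)
        return k

    def pressure_nodal_forces(self, x: np.ndarray, p: float, out: np.ndarray,
                              faces: np.ndarray | None = None,
                              throughput: np.ndarray | None = None) -> None:
        if p == 0.0:
            return
        f_ids = self.pressure_faces if faces is None else faces
        if USE_KERNELS:
            thr = throughput if throughput is not None else np.empty(0)
            fe_kernels.pressure_forces_kernel(
                x, self.tris[f_ids], float(p), out, thr, throughput is not None
            )
            return
        t = self.tris[f_ids]
        d1 = x[t[:, 1]] - x[t[:, 0]]
        d2 = x[t[:, 2]] - x[t[:, 0]]
        va = 0.5 * np.cross(d1, d2)       # atrial-oriented vector area
        if np.any(np.linalg.norm(va, axis=1) < 1e-12):
            raise RuntimeError("degenerate face in pressure load set")
        fn = (p / 3.0) * va
        for k in range(3):
            np.add.at(out, t[:, k], fn)
        if throughput is not None:
            g = np.linalg.norm(fn, axis=1)
            for k in range(3):
                np.add.at(throughput, t[:, k], g)


# ================================================================== contact

class _ContactHandler:
    """Penalty contact state for one stage (candidate lists + rough anchors)."""

    def __init__(self, model: FEModel, cfg: SolverConfig):
        self.model = model
        self.cfg = cfg
        pair = model.leaflet_pair
        self.sides = [
            (pair.nodes_a, pair.tris_b),
            (pair.nodes_b, pair.tris_a),
        ]
        self.shell = pair.shell
        self.cand: list[tuple[np.ndarray, np.ndarray]] = [(np.empty(0, np.int64),) * 2] * 2
        self.anchors: list[dict] = [{}, {}]
        # Per-node effective shell: the leaflets are continuous tissue at the
        # commissures, so mesh regions adjacent there sit inside the nominal
        # shell already in the stress-free reference.  Clamping each node's
        # activation distance to 80% of its reference clearance leaves such
        # neighbours force-free at rest while still resisting approach.
        self.shell_eff = np.full(model.n_nodes, self.shell)
        x0 = model.X0
        for nodes, tris in self.sides:
            tv = model.tris[tris]
            cent = x0[tv].mean(axis=1)
            rad = np.linalg.norm(x0[tv] - cent[:, None, :], axis=2).max(axis=1)
            tree = cKDTree(cent)
            r = 2.0 * self.shell + float(rad.max(initial=0.0))
            groups = tree.query_ball_point(x0[nodes], r)
            for k, lst in enumerate(groups):
                nd = int(nodes[k])
                excl = model.node_neighbors[nd]
                cand = [tris[g] for g in lst
                        if not any(vv in excl for vv in model.tris[tris[g]])]
                if not cand:
                    continue
                tvc = model.tris[np.asarray(cand)]
                _, closest = _closest_point_triangle(
                    np.repeat(x0[nd][None, :], len(cand), axis=0),
                    x0[tvc[:, 0]], x0[tvc[:, 1]], x0[tvc[:, 2]],
                )
                d_ref = float(np.linalg.norm(closest - x0[nd], axis=1).min())
                self.shell_eff[nd] = min(self.shell, 0.8 * d_ref)

    def rebuild(self, x: np.ndarray) -> None:
        cfg = self.cfg
        m = self.model
        for s, (nodes, tris) in enumerate(self.sides):
            tv = m.tris[tris]
            cent = x[tv].mean(axis=1)
            rad = np.linalg.norm(x[tv] - cent[:, None, :], axis=2).max(axis=1)
            tree = cKDTree(cent)
            r = self.shell + cfg.contact_margin + float(rad.max(initial=0.0))
            groups = tree.query_ball_point(x[nodes], r)
            ni, ti = [], []
            nbr = m.node_neighbors
            for k, lst in enumerate(groups):
                nd = int(nodes[k])
                excl = nbr[nd]
                for g in lst:
                    tid = tris[g]
                    a, b, c = m.tris[tid]
                    if a in excl or b in excl or c in excl:
                        continue
                    ni.append(nd)
                    ti.append(tid)
            ni = np.asarray(ni, dtype=np.int64)
            ti = np.asarray(ti, dtype=np.int64)
            old = self.anchors[s]
            self.anchors[s] = {
                (int(n), int(t)): old[(int(n), int(t))]
                for n, t in zip(ni, ti)
                if (int(n), int(t)) in old
            }
            self.cand[s] = (ni, ti)

    def forces(self, x: np.ndarray, out: np.ndarray,
               throughput: np.ndarray | None = None,
               record: np.ndarray | None = None) -> None:
        cfg = self.cfg
        m = self.model
        kt_on = cfg.friction == "rough"
        for s, (ni, ti) in enumerate(self.cand):
            if len(ni) == 0:
                continue
            tv = m.tris[ti]
            a, b, c = x[tv[:, 0]], x[tv[:, 1]], x[tv[:, 2]]
            p = x[ni]
            bary, closest = _closest_point_triangle(p, a, b, c)
            diff = p - closest
            dist = np.linalg.norm(diff, axis=1)
            pen = self.shell_eff[ni] - dist
            act = pen > 0.0
            if not np.any(act):
                if kt_on:
                    self.anchors[s] = {}
                continue
            idx = np.nonzero(act)[0]
            d = diff[idx]
            dn = dist[idx]
            nrm = np.cross(b[idx] - a[idx], c[idx] - a[idx])
            nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
            u = np.where(dn[:, None] > 1e-9, d / np.maximum(dn, 1e-9)[:, None], nrm)
            k_n = cfg.penalty * m.trib_area[ni[idx]]
            eps = cfg.contact_smooth * self.shell
            pe = pen[idx]
            fmag = np.where(pe < eps, 0.5 * k_n * pe**2 / max(eps, 1e-12),
                            k_n * (pe - 0.5 * eps))
            f = fmag[:, None] * u
            if kt_on:
                kt = cfg.kt_ratio * k_n
                anchors = self.anchors[s]
                new_anchors = {}
                ft = np.zeros_like(f)
                for row, ci in enumerate(idx):
                    key = (int(ni[ci]), int(ti[ci]))
                    if key in anchors:
                        w = anchors[key]
                    else:
                        w = bary[ci].copy()
                    new_anchors[key] = w
                    anchor_pos = w[0] * a[ci] + w[1] * b[ci] + w[2] * c[ci]
                    delta = p[ci] - anchor_pos
                    delta_t = delta - (delta @ u[row]) * u[row]
                    ft[row] = -kt[row] * delta_t
                self.anchors[s] = new_anchors
                f = f + ft
            np.add.at(out, ni[idx], f)
            w = bary[idx]
            for k in range(3):
                np.add.at(out, tv[idx, k], -w[:, k:k + 1] * f)
            if throughput is not None:
                g = np.linalg.norm(f, axis=1)
                np.add.at(throughput, ni[idx], g)
                for k in range(3):
                    np.add.at(throughput, tv[idx, k], w[:, k] * g)
            if record is not None:
                np.add.at(record, ni[idx], f)
                for k in range(3):
                    np.add.at(record, tv[idx, k], -w[:, k:k + 1] * f)

    def stiffness(self, k: np.ndarray) -> None:
        cfg = self.cfg
        m = self.model
        for nodes, _ in self.sides:
            k[nodes] += cfg.penalty * m.trib_area[nodes] * (1.0 + cfg.kt_ratio)


def _closest_point_triangle(p, a, b, c):
    """Vectorized closest point on triangle (returns barycentric + point)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    n = len(p)
    bary = np.zeros((n, 3))
    done = np.zeros(n, dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    bary[m] = [1.0, 0.0, 0.0]
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)
    bary[m] = [0.0, 1.0, 0.0]
    done |= m

    m = ~done & (d6 >= 0) & (d5 <= d6)
    bary[m] = [0.0, 0.0, 1.0]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = np.where(m, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    bary[m, 0] = 1.0 - v[m]
    bary[m, 1] = v[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.where(m, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0)
    bary[m, 0] = 1.0 - w[m]
    bary[m, 2] = w[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(m, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    bary[m, 1] = 1.0 - w[m]
    bary[m, 2] = w[m]
    done |= m

    m = ~done
    denom = np.where(va + vb + vc == 0, 1.0, va + vb + vc)
    v = vb / denom
    w = vc / denom
    bary[m, 0] = (1.0 - v - w)[m]
    bary[m, 1] = v[m]
    bary[m, 2] = w[m]

    closest = bary[:, 0:1] * a + bary[:, 1:2] * b + bary[:, 2:3] * c
    return bary, closest


# ================================================================== driver

def internal_forces(model: FEModel, x: np.ndarray) -> np.ndarray:
    """Elastic (membrane + cable) nodal forces = -dE/dx (mN)."""
    out = np.zeros_like(x)
    model.membrane_forces(x, out)
    model.cable_forces(x, out)
    return out


def pressure_forces(model: FEModel, x: np.ndarray, p: float,
                    faces: np.ndarray | None = None) -> np.ndarray:
    """Follower pressure load on the ventricular leaflet surface (mN)."""
    out = np.zeros_like(x)
    model.pressure_nodal_forces(x, p, out, faces=faces)
    return out


def total_elastic_energy(model: FEModel, x: np.ndarray) -> float:
    """Total membrane + cable strain energy (mN*mm); gradient check oracle."""
    t = model.tris
    d1 = x[t[:, 1]] - x[t[:, 0]]
    d2 = x[t[:, 2]] - x[t[:, 0]]
    Ds = np.stack([d1, d2], axis=-1)
    F = Ds @ model.Bm
    C2 = np.einsum("mia,mib->mab", F, F)
    _, _, _, w = membrane_response(
        C2, model.fibers2d, model.matC10, model.matC01,
        model.matk1, model.matk2, model.matkappa, want_energy=True,
    )
    e = float(np.sum(model.A0 * model.thickness * w))
    if len(model.cables):
        a, b = model.cables[:, 0], model.cables[:, 1]
        L = np.linalg.norm(x[b] - x[a], axis=1)
        lam = np.maximum(L / model.cable_L0, 1.0)
        phi = np.zeros_like(lam)
        for mu, alpha in model.mat_chordae.terms:
            phi += mu * (lam**alpha / alpha + (2.0 / alpha) * lam ** (-alpha / 2.0)
                         - 3.0 / alpha)
        e += float(np.sum(model.cable_area * model.cable_L0 * phi))
    return e


def _masses(model: FEModel, x: np.ndarray, contact: _ContactHandler | None,
            cfg: SolverConfig, stage: "Stage | None" = None) -> np.ndarray:
    k = model.membrane_stiffness(x) + model.cable_stiffness(x)
    if contact is not None:
        contact.stiffness(k)
    if stage is not None and stage.anchor_ids is not None:
        k[stage.anchor_ids] += stage.anchor_k
    m = cfg.mass_safety * cfg.dt**2 * k
    return np.maximum(m, 1e-5)


def solve_quasistatic(model: FEModel, x0: np.ndarray, stage: Stage,
                      cfg: SolverConfig | None = None) -> SimState:
    """Relax one procedure step to static equilibrium.

    Prescribed node positions, point loads and the pressure are ramped
    linearly over ``cfg.ramp_steps`` pseudo-time steps, then the system is
    relaxed until the residual criterion is met (or ``max_steps`` is hit,
    which raises in strict mode and warns otherwise).
    """
    cfg = cfg or SolverConfig()
    x = x0.copy()
    v = np.zeros_like(x)
    con = stage.constrained()
    free = np.ones(model.n_nodes, dtype=bool)
    free[con] = False

    x_start = x[stage.prescribed_ids].copy()
    contact = _ContactHandler(model, cfg) if stage.contact else None

    masses = _masses(model, x, contact, cfg, stage)
    ke_prev = 0.0
    history: list[tuple[int, float, float]] = []
    converged = False
    res = np.inf
    rel = np.inf
    step = 0

    loads = stage.point_loads

    for step in range(1, cfg.max_steps + 1):
        s = min(1.0, step / cfg.ramp_steps)
        if len(stage.prescribed_ids):
            x[stage.prescribed_ids] = x_start + s * (stage.prescribed_targets - x_start)

        if contact is not None and (step - 1) % cfg.broadphase_every == 0:
            contact.rebuild(x)
        if step % cfg.mass_update == 0:
            masses = np.maximum(masses, _masses(model, x, contact, cfg, stage))

        check = step % cfg.check_every == 0
        f = np.zeros_like(x)
        thr = np.zeros(model.n_nodes) if check else None
        model.membrane_forces(x, f, throughput=thr)
        model.cable_forces(x, f, throughput=thr)
        if stage.pressure:
            model.pressure_nodal_forces(x, s * stage.pressure, f, throughput=thr)
        if loads is not None:
            # constant (dead) point loads: applied at full value from the
            # first step so a BC release replaced by its reaction stays in
            # equilibrium exactly
            f += loads
            if thr is not None:
                thr += np.linalg.norm(loads, axis=1)
        if contact is not None:
            contact.forces(x, f, throughput=thr)
        if stage.anchor_ids is not None and stage.anchor_k > 0:
            fa = -stage.anchor_k * (x[stage.anchor_ids] - stage.anchor_ref)
            f[stage.anchor_ids] += fa
            if thr is not None:
                thr[stage.anchor_ids] += np.linalg.norm(fa, axis=1)

        v[free] += (cfg.dt / masses[free, None]) * f[free]
        if cfg.viscous:
            v[free] *= 1.0 - cfg.viscous
        speed = np.linalg.norm(v, axis=1)
        fast = speed > cfg.vmax / cfg.dt
        if np.any(fast):
            v[fast] *= (cfg.vmax / cfg.dt) / speed[fast, None]
        ke = float(np.sum(masses[free] * np.einsum("ij,ij->i", v[free], v[free])))
        if ke < ke_prev:
            v[:] = 0.0
            ke = 0.0
        ke_prev = ke
        x[free] += cfg.dt * v[free]

        if check:
            rnorm = np.linalg.norm(f[free], axis=1)
            res = float(np.sqrt(np.mean(rnorm**2))) if rnorm.size else 0.0
            scale = float(np.sqrt(np.mean(thr[free] ** 2))) if rnorm.size else 1.0
            rel = res / max(scale, 1e-12)
            # pressurized stages additionally require the global balance
            # (sum of reactions + net applied load) to close, since the
            # residual sum is what the equilibrium audit measures
            balance_ok = True
            if stage.pressure and rnorm.size:
                fp = np.zeros_like(x)
                model.pressure_nodal_forces(x, s * stage.pressure, fp)
                net = float(np.linalg.norm(fp.sum(axis=0)))
                gsum = float(np.linalg.norm(f[free].sum(axis=0)))
                balance_ok = gsum < max(cfg.balance_tol * net, cfg.floor_force)
            history.append((step, res, rel))
            if s >= 1.0 and balance_ok and (res < cfg.floor_force or rel < cfg.tol_rel):
                converged = True
                break

    if not converged:
        msg = (f"dynamic relaxation did not settle in {cfg.max_steps} steps "
               f"(residual {res:.3g} mN, relative {rel:.3g})")
        if cfg.strict:
            raise ConvergenceError(msg, history)
        import warnings

        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    # final force pass populating derived quantities and reactions
    f = np.zeros_like(x)
    collect: dict = {}
    contact_rec = np.zeros_like(x)
    model.membrane_forces(x, f, collect=collect)
    model.cable_forces(x, f, collect=collect)
    if stage.pressure:
        model.pressure_nodal_forces(x, stage.pressure, f)
    if loads is not None:
        f += loads
    if contact is not None:
        contact.forces(x, f, record=contact_rec)
    if stage.anchor_ids is not None and stage.anchor_k > 0:
        f[stage.anchor_ids] += -stage.anchor_k * (x[stage.anchor_ids] - stage.anchor_ref)

    reactions = np.zeros_like(x)
    reactions[con] = -f[con]

    S2 = collect["S2"]
    F = collect["F"]
    lam3 = collect["lam3"]
    sigma = np.einsum("mia,mab,mjb->mij", F, S2, F)  # Cauchy (J=1), 3x3 rank-2
    eig = np.linalg.eigvalsh(sigma)
    stress_max = eig[:, -1]
    C2 = collect["C2"]
    E2 = 0.5 * (C2 - np.eye(2))
    ev = np.linalg.eigvalsh(E2)
    strain_inplane = ev[:, -1]
    strain_thick = 0.5 * (lam3**2 - 1.0)
    strain_max = np.maximum(strain_inplane, strain_thick)

    rnorm = np.linalg.norm(f[free], axis=1)
    return SimState(
        x=x,
        v=v,
        reactions=reactions,
        constrained=con,
        cable_stretch=collect.get("cable_stretch", np.empty(0)),
        cable_tension=collect.get("cable_tension", np.empty(0)),
        contact_force=contact_rec,
        tri_stress_max=stress_max,
        tri_strain_max=strain_max,
        tri_F=F,
        residual=float(np.sqrt(np.mean(rnorm**2))) if rnorm.size else 0.0,
        residual_rel=rel,
        converged=converged,
        steps=step,
        history=history,
        applied_pressure=stage.pressure,
    )


def reaction_forces(state: SimState, node_ids: np.ndarray) -> np.ndarray:
    """Reaction force vectors (mN) on displacement-constrained nodes."""
    node_ids = np.asarray(node_ids, dtype=np.int64)
    con = set(int(i) for i in state.constrained)
    missing = [int(i) for i in node_ids if int(i) not in con]
    if missing:
        raise ValueError(f"nodes {missing[:5]} are not displacement-constrained")
    return state.reactions[node_ids]
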