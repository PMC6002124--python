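"""Outcome measures: annular dimensions, cut-plane coaptation metrics,
projected orifice area, contact summaries and patch statistics."""

import numpy as np
import pytest

from mvrepair import metrics as mx
from mvrepair.geometry import axis_angle_rotation
from mvrepair.valve import build_valve

from conftest import grid_sheet, make_sheet


class _State:
    """Minimal state shim for purely geometric metric tests."""

    def __init__(self, x, pm_tips=None, contact=None, stress=None, strain=None,
                 F=None):
        self.x = np.asarray(x, dtype=float)
        self.pm_tips = pm_tips or {}
        self.contact_force = contact if contact is not None else np.zeros_like(self.x)
        self.tri_stress_max = stress
        self.tri_strain_max = strain
        self.tri_F = F


def circle_valve(radius=10.0, n=72):
    """A planar circular 'annulus' carrying only loop/landmark structure."""

    class LoopValve:
        pass

    th = 2 * np.pi * np.arange(n) / n
    v = LoopValve()
    v.nodes = np.column_stack([radius * np.cos(th), radius * np.sin(th), np.zeros(n)])
    v.annulus_loop = np.arange(n)
    v.landmarks = {
        "saddle_horn": 0,
        "mid_posterior": n // 2,
        "lateral_commissure": n // 4,
        "septal_commissure": 3 * n // 4,
    }
    return v


class TestAnnulusMeasurements:
    def test_circle_analytic(self):
        n = 72
        v = circle_valve(radius=10.0, n=n)
        ic, sl, area = mx.annulus_measurements(v.nodes, v)
        assert ic == pytest.approx(20.0, abs=1e-12)
        assert sl == pytest.approx(20.0, abs=1e-12)
        # exact area of the inscribed regular n-gon
        assert area == pytest.approx(0.5 * n * 100 * np.sin(2 * np.pi / n), rel=1e-12)
        # converges to the circle area with resolution
        v2 = circle_valve(radius=10.0, n=1440)
        assert mx.annulus_measurements(v2.nodes, v2)[2] == pytest.approx(
            np.pi * 100, rel=1e-5)

    def test_saddle_loop_projected_area_matches_raster_oracle(self):
        v = circle_valve(radius=10.0, n=144)
        x = v.nodes.copy()
        th = 2 * np.pi * np.arange(len(x)) / len(x)
        x[:, 2] = 2.0 * np.cos(2 * th)
        _, _, area = mx.annulus_measurements(x, v)
        # raster oracle on the z-projection (LS plane is z=0 by symmetry)
        res = 0.02
        gx, gy = np.meshgrid(np.arange(-11, 11, res), np.arange(-11, 11, res))
        inside = gx**2 + gy**2 <= 100.0
        raster = inside.sum() * res**2
        assert area == pytest.approx(raster, rel=1e-3)

    def test_rigid_motion_invariance(self):
        v = circle_valve()
        R = axis_angle_rotation([0.4, 0.2, 0.9], 1.1)
        x2 = v.nodes @ R.T + np.array([5.0, 6.0, -2.0])
        a = mx.annulus_measurements(v.nodes, v)
        b = mx.annulus_measurements(x2, v)
        assert np.allclose(a, b, rtol=1e-9)

    def test_missing_landmark_reported(self):
        v = circle_valve()
        del v.landmarks["mid_posterior"]
        with pytest.raises(ValueError, match="mid_posterior"):
            mx.annulus_measurements(v.nodes, v)


class TestPercentReduction:
    @pytest.mark.parametrize("baseline,value,expected", [
        (944.693, 594.35, 37.09),   # printed worked example
        (944.693, 811.67, 14.08),
        (39.1, 33.94, 13.20),
        (33.51, 21.97, 34.44),
        (33.51, 15.09, 54.97),
        (39.1, 37.16, 4.96),
    ])
    def test_worked_examples(self, baseline, value, expected):
        assert mx.percent_reduction(baseline, value) == expected

    def test_identity_is_zero(self):
        assert mx.percent_reduction(17.3, 17.3) == 0.0

    def test_negative_when_value_exceeds_baseline(self):
        # formula gives -4.65 for the printed pair (39.1, 40.92)
        assert mx.percent_reduction(39.1, 40.92) == -4.65

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            mx.percent_reduction(0.0, 1.0)


class TestCutplaneMetrics:
    @staticmethod
    def _constructed_sheets(strip=6.0, depth=4.0, gap=None):
        """Two sheets on the A2-P2 section.  With ``gap`` None they descend
        steeply and meet over a coincident horizontal strip of width
        ``strip`` at ``depth`` mm below the annular plane; with ``gap`` set
        they stop short, leaving that horizontal gap between their tips at
        ``depth``."""

        class TwoSheets:
            pass

        ny = 9
        ys = np.linspace(-10, 10, ny)
        if gap is None:
            h = strip / 2.0
            xa = np.array([15.0, 10.0, h + 2.0, h, h / 2, 0.0, -h / 2, -h])
            za = np.array([2.0, 0.5, -1.0, -depth, -depth, -depth, -depth, -depth])
        else:
            xa = np.linspace(15.0, gap / 2.0, 8)
            za = np.linspace(2.0, -depth, 8)
        xp, zp = -xa, za  # mirror for the posterior sheet

        def sheet(xs, zs):
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            Z = np.repeat(np.asarray(zs)[:, None], ny, axis=1)
            nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
            tris = []
            for i in range(len(xs) - 1):
                for j in range(ny - 1):
                    n00 = i * ny + j
                    n10 = (i + 1) * ny + j
                    n01 = i * ny + j + 1
                    n11 = (i + 1) * ny + j + 1
                    tris.append([n00, n10, n11])
                    tris.append([n00, n11, n01])
            return nodes, np.asarray(tris)

        na, ta = sheet(xa, za)
        np_, tp = sheet(xp, zp)
        v = TwoSheets()
        v.nodes = np.vstack([na, np_])
        v.tris = np.vstack([ta, tp + len(na)])
        v.tri_region = np.concatenate([np.zeros(len(ta), np.int64),
                                       np.ones(len(tp), np.int64)])
        v.thickness = np.full(len(v.tris), 0.8)
        # annulus ring far outside, planar z=0, for the plane/landmarks
        n = 72
        th = 2 * np.pi * np.arange(n) / n
        ring = np.column_stack([16 * np.cos(th), 12 * np.sin(th), np.zeros(n)])
        base = len(v.nodes)
        v.nodes = np.vstack([v.nodes, ring])
        v.annulus_loop = base + np.arange(n)
        v.landmarks = {"saddle_horn": base, "mid_posterior": base + n // 2,
                       "lateral_commissure": base + n // 4,
                       "septal_commissure": base + 3 * n // 4}
        return v

    def test_constructed_overlap_geometry(self):
        """Sheets meeting over a 6 mm coincident strip 4 mm below the plane.

        With the distance-threshold classifier (tolerance tol = 1.0 mm for
        0.8 mm sheets) the coapted zone extends one tolerance up the
        anterior flank: expected length = 6 + tol and expected depth =
        4 - tol*sin(flank angle 56 deg) = 3.17 mm."""
        v = self._constructed_sheets(strip=6.0, depth=4.0)
        depth, length, tenting = mx.cutplane_metrics(_State(v.nodes), v)
        assert depth == pytest.approx(3.17, abs=0.3)
        assert length == pytest.approx(7.0, rel=0.1)
        assert tenting > 10.0

    def test_non_coapting_sections(self):
        v = self._constructed_sheets(depth=5.0, gap=8.0)  # 8 mm gap at -5 mm
        depth, length, tenting = mx.cutplane_metrics(_State(v.nodes), v)
        assert length == 0.0
        assert depth == pytest.approx(5.0, rel=0.12)
        assert tenting > 0.0

    def test_resolution_oracle(self, default_sweep):
        """Cut-plane metrics are stable when the section is sampled 10x more
        densely."""
        valve = default_sweep["_valve"]
        st = default_sweep["classic36"]["case"].closed
        d1, l1, t1 = mx.cutplane_metrics(st, valve, n_samples=400)
        d2, l2, t2 = mx.cutplane_metrics(st, valve, n_samples=4000)
        assert l2 == pytest.approx(l1, rel=0.02, abs=0.2)
        assert d2 == pytest.approx(d1, rel=0.02, abs=0.05)
        assert t2 == pytest.approx(t1, rel=0.02, abs=0.5)


class TestOrificeArea:
    def test_covered_annulus_zero(self):
        v = self._disk_valve(hole=False)
        area, sectors = mx.orifice_area_2d(_State(v.nodes), v)
        assert area == 0.0
        assert sectors == []

    def test_punched_hole_recovered(self):
        v = self._disk_valve(hole=True)
        area, sectors = mx.orifice_area_2d(_State(v.nodes), v)
        assert area == pytest.approx(self.HOLE_AREA, rel=0.02)
        assert sectors == ["P2"]

    def test_matches_raster_oracle(self, default_sweep):
        valve = default_sweep["_valve"]
        st = default_sweep["baseline"]["case"].closed
        area, _ = mx.orifice_area_2d(st, valve)
        raster = self._raster_orifice(st, valve, res=0.05)
        assert area == pytest.approx(raster, rel=0.05, abs=1.5)

    HOLE_AREA = 24.0

    @staticmethod
    def _disk_valve(hole: bool):
        """A planar disk of leaflet triangles filling a circular annulus,
        with an optional punched quadrilateral hole in the posterior half."""

        class DiskValve:
            pass

        import shapely
        from shapely.geometry import Polygon

        n, rings = 72, 8
        R = 12.0
        th = 2 * np.pi * np.arange(n) / n
        nodes = []
        for i in range(rings + 1):
            r = R * (1 - i / rings)
            if r == 0:
                nodes.append(np.zeros((1, 3)))
            else:
                nodes.append(np.column_stack([r * np.cos(th), r * np.sin(th),
                                              np.zeros(n)]))
        center_id = sum(len(a) for a in nodes[:-1])
        pts = np.vstack(nodes)
        tris = []
        for i in range(rings - 1):
            for j in range(n):
                jp = (j + 1) % n
                a0, b0 = i * n + j, i * n + jp
                a1, b1 = (i + 1) * n + j, (i + 1) * n + jp
                tris.append([a0, b0, b1])
                tris.append([a0, b1, a1])
        for j in range(n):
            jp = (j + 1) % n
            tris.append([(rings - 1) * n + j, (rings - 1) * n + jp, center_id])
        tris = np.asarray(tris)
        if hole:
            # drop triangles whose centroid lies in a posterior box of known area
            cent = pts[tris].mean(axis=1)
            # box x in [-8, -4], y in [-3, 3] -> 4 x 6 = 24 mm^2
            drop = (cent[:, 0] > -8) & (cent[:, 0] < -4) & (np.abs(cent[:, 1]) < 3)
            kept = tris[~drop]
            polys = [Polygon([tuple(q[:2]) for q in pts[t]]) for t in tris[drop]]
            TestOrificeArea.HOLE_AREA = float(shapely.unary_union(polys).area)
            tris = kept
        v = DiskValve()
        v.nodes = pts
        v.tris = tris
        v.tri_region = np.zeros(len(tris), np.int64)
        v.annulus_loop = np.arange(n)
        v.landmarks = {"saddle_horn": 0, "mid_posterior": n // 2,
                       "lateral_commissure": n // 4,
                       "septal_commissure": 3 * n // 4}
        return v

    @staticmethod
    def _raster_orifice(st, valve, res=0.05):
        from matplotlib.path import Path as MplPath

        from mvrepair.geometry import least_squares_plane

        x = st.x
        ann = x[valve.annulus_loop]
        plane = least_squares_plane(ann)
        basis = plane.basis()
        ann2 = plane.to_2d(ann, basis)
        lo = ann2.min(axis=0) - 1
        hi = ann2.max(axis=0) + 1
        gx, gy = np.meshgrid(np.arange(lo[0], hi[0], res), np.arange(lo[1], hi[1], res))
        pix = np.column_stack([gx.ravel(), gy.ravel()])
        inside = MplPath(ann2).contains_points(pix)
        tri2 = plane.to_2d(x[valve.tris].reshape(-1, 3), basis).reshape(-1, 3, 2)
        covered = np.zeros(len(pix), dtype=bool)
        for t in tri2:
            sub = inside & ~covered
            if not sub.any():
                break
            cand = np.nonzero(sub)[0]
            box = (pix[cand, 0] >= t[:, 0].min()) & (pix[cand, 0] <= t[:, 0].max()) \
                & (pix[cand, 1] >= t[:, 1].min()) & (pix[cand, 1] <= t[:, 1].max())
            cand = cand[box]
            if len(cand) == 0:
                continue
            covered[cand] |= MplPath(t).contains_points(pix[cand])
        return float((inside & ~covered).sum() * res * res)


class TestContactSummary:
    def test_no_contact_zeros(self, default_apparatus):
        valve, _ = default_apparatus
        st = _State(valve.nodes)
        assert mx.contact_summary(st, valve) == (0.0, 0.0, 0.0)

    def test_total_at_least_max(self, default_sweep):
        for label in ("classic32", "geoform38"):
            rep = default_sweep[label]["metrics"]
            assert rep.contact_force_total_mN >= rep.contact_force_max_mN

    def test_penalty_insensitivity(self):
        """Doubling the contact penalty leaves the transmitted contact
        resultant essentially unchanged (penetration halves, the force is
        set by statics).  Audited on the pressed-sheet geometry, where the
        active set is unambiguous."""
        from mvrepair.fe import SolverConfig, Stage, solve_quasistatic
        from test_fe_core import TestContact

        totals = []
        for penalty in (2000.0, 4000.0):
            m, cur, edge_ids, free_lower, tris = TestContact._two_sheets(gap=0.55)
            m.pressure_faces = np.arange(len(tris))
            st = solve_quasistatic(
                m, cur.copy(),
                Stage(fixed=edge_ids, pressure=TestContact.PRESS_P, contact=True),
                SolverConfig(ramp_steps=600, max_steps=16000, tol_rel=1e-4,
                             floor_force=1e-3, penalty=penalty))
            totals.append(st.contact_force[len(cur) // 2:, 2].sum())
        assert totals[1] == pytest.approx(totals[0], rel=0.02)


class TestPmDistances:
    def test_analytic_tip_placement(self):
        v = circle_valve()
        tips = {"APM": np.array([3.0, 4.0, -7.0]), "PPM": np.array([0.0, -4.0, -6.0])}
        inter, apm_ma = mx.pm_distances(_State(v.nodes, pm_tips=tips), v)
        assert apm_ma == pytest.approx(7.0, abs=1e-9)
        assert inter == pytest.approx(np.linalg.norm(tips["APM"] - tips["PPM"]), abs=1e-12)

    def test_rigid_motion_invariance(self):
        v = circle_valve()
        R = axis_angle_rotation([0.2, 0.8, 0.4], 0.9)
        t = np.array([1.0, -5.0, 3.0])
        tips = {"APM": np.array([3.0, 4.0, -7.0]), "PPM": np.array([0.0, -4.0, -6.0])}
        tips2 = {k: v2 @ R.T + t for k, v2 in tips.items()}
        a = mx.pm_distances(_State(v.nodes, pm_tips=tips), v)
        b = mx.pm_distances(_State(v.nodes @ R.T + t, pm_tips=tips2), v)
        assert np.allclose(a, b, atol=1e-9)

    def test_missing_tip_reported(self):
        v = circle_valve()
        with pytest.raises(ValueError, match="tips"):
            mx.pm_distances(_State(v.nodes, pm_tips={"APM": np.zeros(3)}), v)


class TestPatchStats:
    def test_elementwise_recomputation_oracle(self, default_sweep):
        """Patch statistics agree with directly recomputing the principal
        Cauchy stress from the stored deformation gradients."""
        valve = default_sweep["_valve"]
        model = default_sweep["_model"]
        st = default_sweep["classic38"]["case"].closed
        els = valve.patch_elements("PML")
        F = st.tri_F[els]
        C2 = np.einsum("mia,mib->mab", F, F)
        from mvrepair.materials import membrane_response

        S2, _, _ = membrane_response(
            C2, model.fibers2d[els], model.matC10[els], model.matC01[els],
            model.matk1[els], model.matk2[els], model.matkappa[els])
        sigma = np.einsum("mia,mab,mjb->mij", F, S2, F)
        expect = np.linalg.eigvalsh(sigma)[:, -1]
        stats = mx.patch_stats(st, valve)
        assert stats["PML"]["stress_avg"] == pytest.approx(expect.mean(), rel=1e-9)
        assert stats["PML"]["stress_median"] == pytest.approx(np.median(expect), rel=1e-9)

    def test_undeformed_all_zero(self, default_apparatus, default_model):
        valve, _ = default_apparatus
        m = default_model
        x = m.X0
        t = valve.tris
        Ds = np.stack([x[t[:, 1]] - x[t[:, 0]], x[t[:, 2]] - x[t[:, 0]]], axis=-1)
        F = Ds @ m.Bm
        st = _State(x, stress=np.zeros(len(t)), strain=np.zeros(len(t)), F=F)
        stats = mx.patch_stats(st, valve)
        for leaflet in ("AML", "PML"):
            assert stats[leaflet]["stress_avg"] == 0.0
            assert stats[leaflet]["strain_median"] == 0.0

    def test_empty_patch_reported(self, default_sweep):
        import copy

        valve = copy.copy(default_sweep["_valve"])
        valve.midsection_patches = {"AML": np.empty(0, np.int64),
                                    "PML": np.empty(0, np.int64)}
        st = default_sweep["baseline"]["case"].closed
        with pytest.raises(ValueError, match="patch"):
            mx.patch_stats(st, valve)


class TestReportCompleteness:
    def test_all_fields_finite_for_every_case(self, default_sweep):
        for label, rec in default_sweep.items():
            if label.startswith("_"):
                continue
            rec["metrics"].validate()

    def test_metrics_rigid_motion_invariance(self, default_sweep):
        """The full report is invariant under a rigid motion of the closed
        state."""
        import copy

        valve = default_sweep["_valve"]
        st = default_sweep["classic38"]["case"].closed
        R = axis_angle_rotation([0.3, 0.5, 0.8], 0.7)
        t = np.array([8.0, -3.0, 12.0])
        moved = copy.copy(st)
        moved.x = st.x @ R.T + t
        moved.pm_tips = {k: v @ R.T + t for k, v in st.pm_tips.items()}
        moved.tri_F = np.einsum("ij,mjk->mik", R, st.tri_F)
        a = mx.compute_metrics(st, valve).to_dict()
        b = mx.compute_metrics(moved, valve).to_dict()
        for k in a:
            if isinstance(a[k], str):
                assert a[k] == b[k]
            else:
                assert b[k] == pytest.approx(a[k], rel=1e-6, abs=1e-6)
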