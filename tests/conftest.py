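"""Shared fixtures: small analytic FE models and the (session-cached)
repair-pipeline sweep on the default synthetic valve."""

import numpy as np
import pytest

from mvrepair import procedures as proc
from mvrepair.fe import FEModel, SolverConfig
from mvrepair.materials import HGOParams, OgdenParams
from mvrepair.metrics import annulus_measurements, compute_metrics, percent_reduction
from mvrepair.valve import GeneratorParams, build_valve


class _Sheet:
    """Bare-bones valve-like container for analytic membrane tests."""


class _Cables:
    pass


def make_sheet(nodes, tris, thickness=1.0, fibers=None, region=None):
    v = _Sheet()
    v.nodes = np.asarray(nodes, dtype=float)
    v.tris = np.asarray(tris, dtype=np.int64)
    m = len(v.tris)
    v.tri_region = np.zeros(m, dtype=np.int64) if region is None else np.asarray(region)
    v.tri_scallop = v.tri_region.copy()
    v.thickness = np.full(m, float(thickness))
    if fibers is None:
        fibers = np.tile(np.array([[[1.0, 0, 0], [0, 1.0, 0]]]), (m, 1, 1))
    v.fiber_field = np.asarray(fibers, dtype=float)
    return v


def make_cables(origins=(), seg_a=(), seg_b=(), slack=(), area=()):
    c = _Cables()
    c.origins = np.asarray(origins, dtype=float).reshape(-1, 3)
    c.branch_nodes = np.zeros((0, 3))
    c.seg_a = np.asarray(seg_a, dtype=np.int64).reshape(-1, 2)
    c.seg_b = np.asarray(seg_b, dtype=np.int64).reshape(-1, 2)
    c.slack_length = np.asarray(slack, dtype=float)
    c.area = np.asarray(area, dtype=float)
    c.seg_type = np.zeros(len(c.seg_a), dtype=np.int64)
    return c


def grid_sheet(side, n, prestretch=1.0, z=0.0):
    """A square membrane grid; returns (current nodes, reference valve-like,
    index grid)."""
    xs = np.linspace(0.0, side, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    cur = np.column_stack([X.ravel(), Y.ravel(), np.full(n * n, z)])
    ref = cur.copy()
    ref[:, :2] /= prestretch
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            n00 = i * n + j
            n10 = (i + 1) * n + j
            n01 = i * n + j + 1
            n11 = (i + 1) * n + j + 1
            tris.append([n00, n10, n11])
            tris.append([n00, n11, n01])
    return cur, np.asarray(tris, dtype=np.int64), (X, Y)


NEARLY_LINEAR = HGOParams(C10=30.0, C01=0.05, k1=0.0, k2=1.0, kappa=0.0, theta_deg=0.0)
SOFT_CHORD = OgdenParams(terms=((120.0, 10.0), (30.0, 4.0)))


def sheet_model(valve, cables=None, mat=NEARLY_LINEAR, chord=SOFT_CHORD,
                mat_posterior=None):
    return FEModel(valve, cables or make_cables(),
                   {"anterior": mat, "posterior": mat_posterior or mat,
                    "chordae": chord})


# ------------------------------------------------------------------ pipeline

RING_CASES = [("classic", s) for s in (32, 34, 36, 38, 40)] + \
             [("geoform", s) for s in (36, 38)]


def _run_sweep(seed, rings, pmr_rings, prebuilt=None):
    if prebuilt is None:
        valve, chordae = build_valve(GeneratorParams(seed=seed))
        model = proc.make_model(valve, chordae)
        cfg = SolverConfig()
        pre = proc.run_pretension(valve, chordae, model, cfg)
    else:
        valve, chordae, model, cfg, pre = prebuilt
    baseline_area = annulus_measurements(pre.state, valve)[2]
    out = {"_valve": valve, "_chordae": chordae, "_model": model,
           "_pretension": pre, "_baseline_area": baseline_area}
    plans = [proc.ProcedurePlan(ring=None)]
    plans += [proc.ProcedurePlan(ring=r) for r in rings]
    plans += [proc.ProcedurePlan(ring=r, pmr=True) for r in pmr_rings]
    for plan in plans:
        case = proc.run_case(valve, chordae, plan, model, cfg, pretension=pre)
        rep = compute_metrics(case.closed, valve)
        rec = {"case": case, "metrics": rep}
        if case.post_repair is not None:
            area = annulus_measurements(case.post_repair, valve)[2]
            rec["post_area"] = area
            rec["area_reduction_pct"] = percent_reduction(baseline_area, area)
        out[plan.label] = rec
    return out


@pytest.fixture(scope="session")
def default_apparatus():
    return build_valve(GeneratorParams(seed=0))


@pytest.fixture(scope="session")
def default_model(default_apparatus):
    valve, chordae = default_apparatus
    return proc.make_model(valve, chordae)


@pytest.fixture(scope="session")
def pretension_result(default_apparatus, default_model):
    valve, chordae = default_apparatus
    return proc.run_pretension(valve, chordae, default_model, SolverConfig())


@pytest.fixture(scope="session")
def default_sweep(default_apparatus, default_model, pretension_result):
    """Full repair matrix on the default valve (seed 0): baseline, the five
    Classic and two GeoForm rings, each also with adjunct PMR."""
    valve, chordae = default_apparatus
    prebuilt = (valve, chordae, default_model, SolverConfig(), pretension_result)
    return _run_sweep(0, RING_CASES, RING_CASES, prebuilt=prebuilt)


@pytest.fixture(scope="session")
def replicate_sweeps():
    """Reduced repair sets on two further generator seeds, for robustness of
    the directional properties to patient-geometry variation."""
    reduced = [("classic", 38), ("classic", 40)]
    return [_run_sweep(seed, reduced, [("classic", 38)]) for seed in (1, 2)]
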