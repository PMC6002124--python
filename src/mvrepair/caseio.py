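"""Case input/output: meshes, chordae sidecars, metrics tables, manifests.

Surface meshes are written both as Wavefront OBJ (full %.17g precision,
so a write/read round trip — reading via trimesh — reproduces coordinates
bit-exactly) and as legacy ASCII VTK PolyData (readable by ParaView); integer scallop
labels travel as VTK cell data and as a JSON sidecar together with the node
label sets (annulus loop, free edges, midsection patches).  Chordae are a
JSON sidecar (origins, segments, areas, rest lengths, tensions).  Metrics go
to CSV and JSON with a fixed column set; every case directory carries a
manifest with the seed, configuration hash, package version and solver
residuals so any output is reproducible from (config, seed, code version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import __version__
from .metrics import MetricsReport
from .valve import ChordaeNetwork, ValveModel

__all__ = [
    "write_vtk_polydata",
    "write_valve_obj",
    "read_valve_obj",
    "export_case",
    "load_case_metrics",
    "combine_metrics",
]

METRIC_COLUMNS = [f.name for f in MetricsReport.__dataclass_fields__.values()]  # type: ignore[attr-defined]


def write_vtk_polydata(path, points: np.ndarray, polys: np.ndarray,
                       cell_data: dict | None = None,
                       point_data: dict | None = None) -> None:
    """Minimal legacy ASCII VTK PolyData writer (triangles + integer/float
    data arrays)."""
    points = np.asarray(points, dtype=float)
    polys = np.asarray(polys, dtype=np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        "mvrepair surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} double",
    ]
    lines += [" ".join(f"{c:.17g}" for c in p) for p in points]
    lines.append(f"POLYGONS {len(polys)} {4 * len(polys)}")
    lines += ["3 " + " ".join(str(int(i)) for i in t) for t in polys]

    def data_block(kind: str, data: dict) -> None:
        n = len(points) if kind == "POINT_DATA" else len(polys)
        lines.append(f"{kind} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr)
            typ = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            lines.append(f"SCALARS {name} {typ} 1")
            lines.append("LOOKUP_TABLE default")
            fmt = (lambda x: str(int(x))) if typ == "int" else (lambda x: f"{x:.9g}")
            lines.extend(fmt(x) for x in arr)

    if cell_data:
        data_block("CELL_DATA", cell_data)
    if point_data:
        data_block("POINT_DATA", point_data)
    Path(path).write_text("\n".join(lines) + "\n")


def write_valve_obj(path, points: np.ndarray, tris: np.ndarray) -> None:
    """Full-precision OBJ export; %.17g vertex formatting makes the
    write/read round trip bit-exact for float64 coordinates."""
    pts = np.asarray(points, dtype=float)
    faces = np.asarray(tris, dtype=np.int64)
    lines = ["# mvrepair surface"]
    lines += [f"v {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in pts]
    lines += [f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}" for t in faces]
    Path(path).write_text("\n".join(lines) + "\n")


def read_valve_obj(path) -> tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.load(str(path), file_type="obj", process=False,
                        maintain_order=True)
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64)


def _labels_dict(valve: ValveModel) -> dict:
    return {
        "annulus_loop": valve.annulus_loop.tolist(),
        "landmarks": {k: int(v) for k, v in valve.landmarks.items()},
        "free_edge": {k: v.tolist() for k, v in valve.free_edge.items()},
        "midsection_patches": {k: v.tolist() for k, v in valve.midsection_patches.items()},
        "tri_region": valve.tri_region.tolist(),
        "tri_scallop": valve.tri_scallop.tolist(),
    }


def _chordae_dict(chordae: ChordaeNetwork, tensions: np.ndarray | None = None) -> dict:
    d = {
        "origins": chordae.origins.tolist(),
        "origins_pre_shortening": chordae.origins_pre_shortening.tolist(),
        "origin_pm": chordae.origin_pm.tolist(),
        "branch_nodes": chordae.branch_nodes.tolist(),
        "branch_parent_origin": chordae.branch_parent_origin.tolist(),
        "seg_a": chordae.seg_a.tolist(),
        "seg_b": chordae.seg_b.tolist(),
        "slack_length": chordae.slack_length.tolist(),
        "area": chordae.area.tolist(),
        "seg_type": chordae.seg_type.tolist(),
        "tethered_origin_ids": chordae.tethered_origin_ids.tolist(),
        "shortening": chordae.shortening.tolist(),
    }
    if tensions is not None:
        d["tension_mN"] = np.asarray(tensions).tolist()
    return d


def export_case(state, valve: ValveModel, report: MetricsReport, out_dir,
                chordae: ChordaeNetwork | None = None, config: dict | None = None,
                seed: int | None = None, case_id: str = "case") -> dict:
    """Write one converged case: deformed mesh (OBJ + VTK), chordae tensions
    (JSON), metrics (CSV + JSON) and the run manifest.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = state.x[: valve.n_nodes]
    write_valve_obj(out / "leaflets.obj", x, valve.tris)
    write_vtk_polydata(
        out / "leaflets.vtk", x, valve.tris,
        cell_data={
            "region": valve.tri_region,
            "scallop": valve.tri_scallop,
            "stress_max_kPa": state.tri_stress_max,
            "strain_max": state.tri_strain_max,
        },
    )
    (out / "labels.json").write_text(json.dumps(_labels_dict(valve)))
    if chordae is not None:
        (out / "chordae.json").write_text(
            json.dumps(_chordae_dict(chordae, state.cable_tension))
        )
    row = {"case_id": case_id, **report.to_dict()}
    pd.DataFrame([row])[["case_id"] + METRIC_COLUMNS].to_csv(out / "metrics.csv", index=False)
    (out / "metrics.json").write_text(json.dumps(row, indent=1))

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "case_id": case_id,
        "seed": seed,
        "mvrepair_version": __version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "solver_residual_mN": float(state.residual),
        "solver_residual_relative": float(state.residual_rel),
        "converged": bool(state.converged),
        "steps": int(state.steps),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_case_metrics(case_dir) -> pd.DataFrame:
    return pd.read_csv(Path(case_dir) / "metrics.csv")


def combine_metrics(case_dirs, out_csv) -> pd.DataFrame:
    """Concatenate per-case metric rows into one table with a fixed column
    set (one row per case)."""
    rows = [load_case_metrics(d) for d in case_dirs]
    df = pd.concat(rows, ignore_index=True)[["case_id"] + METRIC_COLUMNS]
    df.to_csv(out_csv, index=False)
    return df
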