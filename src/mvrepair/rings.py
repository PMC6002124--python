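"""Parametric annuloplasty ring curve families.

Two families are provided, mirroring the two commercial rings commonly used
for undersized annuloplasty in functional mitral regurgitation:

* ``classic`` — a planar D-shaped ring; septal-lateral depth 0.75 x size.
* ``geoform`` — a 3-D ring that aggressively reduces the midline
  septal-lateral dimension (0.45 x size) and elevates the posterior annulus
  (0.20 x size).  Its planform keeps posterior lateral lobes with a
  mid-posterior anterior indentation, so the enclosed area stays large while
  the A2-P2 chord shrinks.

Nominal size = intercommissural dimension in mm.  Each family carries a
versioned per-size enclosed-area coefficient (``data/rings.yaml``); the
planform fullness exponent is solved at build time so the loop's projected
area on its least-squares plane matches ``coeff * size^2`` exactly.  The
curves are generated in the model frame: origin at the loop centre, +x
toward mid-anterior, +z atrial.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import yaml
from scipy.optimize import brentq

from .geometry import least_squares_plane, projected_polygon_area
from .materials import data_path

SUPPORTED_FAMILIES = ("classic", "geoform")
SUPPORTED_SIZES = (32, 34, 36, 38, 40)

__all__ = ["RingGeometry", "build_ring", "SUPPORTED_FAMILIES", "SUPPORTED_SIZES"]


@lru_cache(maxsize=1)
def _ring_table() -> dict:
    with open(data_path("rings.yaml")) as fh:
        return yaml.safe_load(fh)


@dataclass
class RingGeometry:
    """A closed 3-D annuloplasty ring curve with mid-anterior / mid-posterior
    landmarks."""

    family: str
    nominal_size: int
    curve: np.ndarray  # (n, 3), ordered, closed implicitly
    mid_anterior_idx: int
    mid_posterior_idx: int

    def enclosed_area(self) -> float:
        """Projected area [mm^2] of the loop on its least-squares plane."""
        return projected_polygon_area(self.curve)

    def plane(self):
        return least_squares_plane(self.curve)

    def planarity_residual(self) -> float:
        """Max orthogonal distance [mm] of curve points from the LS plane."""
        pl = self.plane()
        return float(np.max(np.abs(pl.signed_distance(self.curve))))

    def posterior_elevation(self) -> float:
        """Elevation [mm] of the mid-posterior landmark above the LS plane."""
        pl = self.plane()
        return float(pl.signed_distance(self.curve[self.mid_posterior_idx]))

    def septal_lateral_span(self) -> float:
        return float(
            np.linalg.norm(self.curve[self.mid_anterior_idx] - self.curve[self.mid_posterior_idx])
        )

    def intercommissural_span(self) -> float:
        n = len(self.curve)
        return float(np.linalg.norm(self.curve[n // 4] - self.curve[3 * n // 4]))

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "RingGeometry":
        return RingGeometry(
            self.family,
            self.nominal_size,
            self.curve @ np.asarray(R).T + np.asarray(t),
            self.mid_anterior_idx,
            self.mid_posterior_idx,
        )


def _wrap_pi(x: np.ndarray) -> np.ndarray:
    return (x + np.pi) % (2 * np.pi) - np.pi


def _planform(theta: np.ndarray, size: float, fam: dict, q: float) -> np.ndarray:
    """(x, y) planform of a ring family at fullness exponent q."""
    b = size / 2.0
    if fam.get("lobe_sl_ratio"):
        sl_depth = fam["lobe_sl_ratio"] * size
    else:
        sl_depth = fam["sl_ratio"] * size
    a_ant = fam["anterior_fraction"] * sl_depth
    a_post = sl_depth - a_ant
    c = np.cos(theta)
    x = np.where(c >= 0, a_ant * np.abs(c) ** q, -a_post * np.abs(c) ** q)
    indent = sl_depth - fam["sl_ratio"] * size
    if indent > 0:
        s = fam["indent_width_rad"]
        x = x + indent * np.exp(-0.5 * (_wrap_pi(theta - np.pi) / s) ** 2)
    y = b * np.sin(theta)
    return np.stack([x, y], axis=-1)


def _elevation(theta: np.ndarray, size: float, fam: dict) -> np.ndarray:
    h = fam.get("elevation_ratio", 0.0) * size
    if h == 0.0:
        return np.zeros_like(theta)
    s = fam["elevation_width_rad"]
    return h * np.exp(-0.5 * (_wrap_pi(theta - np.pi) / s) ** 2)


def _curve_at(q: float, size: float, fam: dict, n: int) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    xy = _planform(theta, size, fam, q)
    z = _elevation(theta, size, fam)
    pts = np.column_stack([xy, z])
    return pts - pts.mean(axis=0)


def build_ring(family: str, nominal_size: int, n_points: int = 128) -> RingGeometry:
    """Build an annuloplasty ring curve of a family and nominal size.

    The fullness exponent of the planform is solved so that the enclosed
    (least-squares-plane projected) area equals the family's calibrated
    ``coeff * size^2``.

    Raises
    ------
    ValueError
        for an unsupported family or size (listing the supported ones).
    """
    family = str(family).lower()
    if family not in SUPPORTED_FAMILIES:
        raise ValueError(f"unsupported ring family {family!r}; supported: {SUPPORTED_FAMILIES}")
    if nominal_size not in SUPPORTED_SIZES:
        raise ValueError(
            f"unsupported ring size {nominal_size} for family {family!r}; "
            f"supported sizes: {SUPPORTED_SIZES}"
        )
    if n_points < 64:
        raise ValueError("ring curves need at least 64 points")
    fam = _ring_table()[family]
    target = fam["area_coeff"][int(nominal_size)] * nominal_size**2

    def area_err(q: float) -> float:
        return projected_polygon_area(_curve_at(q, nominal_size, fam, 512)) - target

    # enclosed area decreases monotonically with the fullness exponent
    q = brentq(area_err, 0.2, 6.0, xtol=1e-10)
    curve = _curve_at(q, nominal_size, fam, n_points)
    # re-solve tiny residual from sampling resolution difference
    ring = RingGeometry(family, int(nominal_size), curve, 0, n_points // 2)
    scale = np.sqrt(target / ring.enclosed_area())
    pl = ring.plane()
    u, v = pl.basis()
    inplane = pl.to_2d(curve, (u, v)) * scale
    d = pl.signed_distance(curve)
    curve = pl.point + inplane[:, :1] * u + inplane[:, 1:2] * v + d[:, None] * pl.normal
    return RingGeometry(family, int(nominal_size), curve, 0, n_points // 2)
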