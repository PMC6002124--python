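"""Planes, polygon areas and rigid-motion helpers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if not np.isfinite(nn) or nn == 0:
            raise ValueError("plane normal must be a nonzero vector")
        object.__setattr__(self, "normal", n / nn)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.point) @ self.normal
        return d if np.asarray(points).ndim > 1 else d[0]

    def project(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection of points onto the plane."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.point) @ self.normal
        out = pts - d[:, None] * self.normal
        return out if np.asarray(points).ndim > 1 else out[0]

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions (deterministic choice)."""
        n = self.normal
        seed = np.array([1.0, 0.0, 0.0])
        if abs(n @ seed) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = seed - (seed @ n) * n
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def to_2d(self, points: np.ndarray, basis: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
        u, v = basis if basis is not None else self.basis()
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.point
        out = np.stack([pts @ u, pts @ v], axis=-1)
        return out if np.asarray(points).ndim > 1 else out[0]


def least_squares_plane(points: np.ndarray, orient: np.ndarray | None = None) -> Plane:
    """Plane minimizing the sum of squared orthogonal distances to ``points``.

    The normal is the singular vector of the centred point cloud with the
    smallest singular value.  ``orient`` (default +z, the atrial direction of
    the model frame) fixes the sign of the normal.

    Raises
    ------
    ValueError
        for fewer than 3 points or a (near-)collinear cloud.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("least_squares_plane needs an (n>=3, 3) point array")
    c = pts.mean(axis=0)
    q = pts - c
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("points are collinear or degenerate; plane is not defined")
    n = vt[2]
    ref = np.array([0.0, 0.0, 1.0]) if orient is None else np.asarray(orient, dtype=float)
    if n @ ref < 0:
        n = -n
    return Plane(c, n)


def polygon_area_2d(xy: np.ndarray) -> float:
    """Absolute area of a closed 2-D polygon (shoelace formula)."""
    p = np.asarray(xy, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def projected_polygon_area(loop_points: np.ndarray, plane: Plane | None = None) -> float:
    """Area of a 3-D closed loop projected onto a plane (default: its own
    least-squares plane)."""
    pts = np.asarray(loop_points, dtype=float)
    if plane is None:
        plane = least_squares_plane(pts)
    return polygon_area_2d(plane.to_2d(pts))


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation matrix taking unit vector ``a`` onto unit vector ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if c < -1 + 1e-12:  # antiparallel: rotate pi about any orthogonal axis
        axis = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            axis = np.array([0.0, 1.0, 0.0])
        axis -= (axis @ a) * a
        axis /= np.linalg.norm(axis)
        return axis_angle_rotation(axis, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def axis_angle_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def polyline_arclength(points: np.ndarray, closed: bool = False) -> np.ndarray:
    """Cumulative arc length along a polyline; first entry is 0."""
    p = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if closed:
        s = np.append(s, s[-1] + np.linalg.norm(p[0] - p[-1]))
    return s


def resample_closed_curve(points: np.ndarray, n: int, s0: float = 0.0) -> np.ndarray:
    """``n`` points uniform in arc length along a closed 3-D curve, starting at
    arc-length offset ``s0`` from the first input point."""
    p = np.asarray(points, dtype=float)
    s = polyline_arclength(p, closed=True)
    total = s[-1]
    loop = np.vstack([p, p[:1]])
    targets = (s0 + np.arange(n) * total / n) % total
    out = np.empty((n, 3))
    for k, t in enumerate(targets):
        i = int(np.searchsorted(s, t, side="right") - 1)
        i = min(i, len(loop) - 2)
        f = (t - s[i]) / max(s[i + 1] - s[i], 1e-300)
        out[k] = (1 - f) * loop[i] + f * loop[i + 1]
    return out
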