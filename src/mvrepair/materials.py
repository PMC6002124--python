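"""Constitutive laws for the mitral apparatus.

Leaflet (and LV) tissue follows an anisotropic hyperelastic strain-energy
function of Holzapfel type with two fiber families and a dispersion
parameter::

    W = C10*(exp(C01*(I1'-3)) - 1)
      + k1/(2*k2) * sum_i ( exp(k2*(kappa*I1' + (1-3*kappa)*I4i' - 1)^2) - 1 )
      + (1/D)*(J-1)^2

where I1' is the first isochoric invariant, I4i' the squared isochoric
stretch along fiber family i, J = det F, and kappa in [0, 1/3] describes
fiber dispersion (kappa = 1/3 makes the fiber term isotropic).  Each fiber
family contributes only while its pseudo-invariant argument
``kappa*I1' + (1-3*kappa)*I4i' - 1`` is tensile — the standard switch that
prevents unphysical compressive fiber stiffening.

Chordae tendineae follow an incompressible one-term-per-pair isotropic Ogden
law reduced to uniaxial tension; chords carry no compression.

Membrane (leaflet) stress uses the exact plane-stress reduction of the
incompressible limit: the through-thickness stretch follows from J = 1 and
the reaction pressure is eliminated in closed form so that the normal stress
vanishes identically.  The volumetric penalty 1/D then never enters the
leaflet response and is retained only for full 3-D states.

Units: lengths mm, stresses kPa, forces mN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "HGOParams",
    "OgdenParams",
    "DeformationState",
    "hgo_energy",
    "hgo_membrane_stress",
    "membrane_response",
    "ogden_fiber_tension",
    "ogden_tangent_stiffness",
    "load_hgo_params",
    "load_ogden_params",
    "data_path",
]

_DATA_DIR = Path(__file__).parent / "data"


def data_path(name: str) -> Path:
    """Path of a parameter file shipped with the package."""
    return _DATA_DIR / name


@dataclass(frozen=True)
class HGOParams:
    """Holzapfel-type material constants.

    C10 [kPa] and C01 [-] set the exponential isotropic matrix; k1 [kPa] and
    k2 [-] the exponential fiber families; kappa in [0, 1/3] the fiber
    dispersion; theta_deg the fiber half-angle to the local circumferential
    axis; D [1/kPa] the volumetric penalty (3-D states only); rho the density
    in g/cm^3.
    """

    C10: float
    C01: float
    k1: float
    k2: float
    kappa: float
    theta_deg: float
    D: float = 5e-4
    rho: float = 1.1

    def __post_init__(self) -> None:
        if self.C10 < 0 or self.k1 < 0:
            raise ValueError("C10 and k1 must be >= 0")
        if self.k2 <= 0:
            raise ValueError("k2 must be > 0")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12:
            raise ValueError("kappa must lie in [0, 1/3]")
        if self.D <= 0:
            raise ValueError("D must be > 0")
        if not 0.0 <= self.theta_deg <= 90.0:
            raise ValueError("theta_deg must lie in [0, 90]")


@dataclass(frozen=True)
class OgdenParams:
    """Ogden pairs (mu_i [kPa], alpha_i [-]); the uniaxial Cauchy stress is
    sigma(lam) = sum_i mu_i*(lam**alpha_i - lam**(-alpha_i/2))."""

    terms: tuple[tuple[float, float], ...]
    rho: float = 1.1

    def __post_init__(self) -> None:
        shear = sum(mu * alpha for mu, alpha in self.terms)
        if shear <= 0:
            raise ValueError("sum(mu_i * alpha_i) must be > 0 (small-strain shear modulus)")


@dataclass
class DeformationState:
    """A pointwise deformation: gradient F plus the two reference fiber
    directions (unit vectors)."""

    F: np.ndarray
    a01: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    a02: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float).reshape(3, 3)
        self.a01 = np.asarray(self.a01, dtype=float) / np.linalg.norm(self.a01)
        self.a02 = np.asarray(self.a02, dtype=float) / np.linalg.norm(self.a02)
        if self.J <= 0:
            raise ValueError("invalid deformation: det F <= 0")

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def I1_bar(self) -> float:
        return float(np.trace(self.C)) * self.J ** (-2.0 / 3.0)

    def I4_bar(self, i: int) -> float:
        a = self.a01 if i == 1 else self.a02
        return float(a @ self.C @ a) * self.J ** (-2.0 / 3.0)


def _fiber_terms(I1: np.ndarray, I4: np.ndarray, p: HGOParams):
    """Pseudo-invariant argument E_i and its tension-only activation mask."""
    E = p.kappa * I1 + (1.0 - 3.0 * p.kappa) * I4 - 1.0
    active = E > 0.0
    return E, active


def hgo_energy(state: DeformationState, p: HGOParams) -> float:
    """Strain-energy density [kPa] of the Holzapfel-type law at a 3-D state."""
    J = state.J
    I1b = state.I1_bar
    w = p.C10 * (np.exp(p.C01 * (I1b - 3.0)) - 1.0)
    for i in (1, 2):
        E, active = _fiber_terms(np.asarray(I1b), np.asarray(state.I4_bar(i)), p)
        if active:
            w += p.k1 / (2.0 * p.k2) * (np.exp(p.k2 * E**2) - 1.0)
    w += (1.0 / p.D) * (J - 1.0) ** 2
    return float(w)


def membrane_response(
    C2: np.ndarray,
    fibers2d: np.ndarray,
    C10: np.ndarray,
    C01: np.ndarray,
    k1: np.ndarray,
    k2: np.ndarray,
    kappa: np.ndarray,
    want_energy: bool = False,
):
    """Vectorized plane-stress response of the incompressible Holzapfel law.

    Parameters
    ----------
    C2 : (..., 2, 2) in-plane right Cauchy-Green tensors.
    fibers2d : (..., 2, 2) the two unit fiber directions (rows) expressed in
        the element's in-plane reference frame.
    C10..kappa : scalars or (...,) arrays of material constants.

    Returns
    -------
    S2 : (..., 2, 2) in-plane 2nd Piola-Kirchhoff stress [kPa]
    lam3 : (...,) through-thickness stretch from J = 1
    stiff : (...,) a tangent-modulus bound [kPa] used for solver mass scaling
    w : (...,) energy density [kPa] (only when ``want_energy``)
    """
    C2 = np.asarray(C2, dtype=float)
    det = C2[..., 0, 0] * C2[..., 1, 1] - C2[..., 0, 1] * C2[..., 1, 0]
    if np.any(det <= 0):
        raise ValueError("invalid membrane deformation: det(C_2d) <= 0")
    lam3sq = 1.0 / det
    I1 = C2[..., 0, 0] + C2[..., 1, 1] + lam3sq

    a1 = fibers2d[..., 0, :]
    a2 = fibers2d[..., 1, :]
    # I4_i = a_i . C2 . a_i
    def _I4(a):
        return (
            a[..., 0] * (C2[..., 0, 0] * a[..., 0] + C2[..., 0, 1] * a[..., 1])
            + a[..., 1] * (C2[..., 1, 0] * a[..., 0] + C2[..., 1, 1] * a[..., 1])
        )

    I41, I42 = _I4(a1), _I4(a2)

    expm = np.exp(np.clip(C01 * (I1 - 3.0), -80.0, 80.0))
    psi1 = C10 * C01 * expm  # dW/dI1, matrix part
    dpsi1 = C10 * C01**2 * expm

    def _fiber(I4):
        E = kappa * I1 + (1.0 - 3.0 * kappa) * I4 - 1.0
        act = E > 0.0
        g = np.exp(np.clip(k2 * E**2, 0.0, 80.0))
        psi = np.where(act, k1 * E * g, 0.0)  # dW/dE
        dpsi = np.where(act, k1 * g * (1.0 + 2.0 * k2 * E**2), 0.0)
        return E, psi, dpsi

    E1, psif1, dpsif1 = _fiber(I41)
    E2, psif2, dpsif2 = _fiber(I42)

    w1 = psi1 + kappa * (psif1 + psif2)  # total dW/dI1
    w41 = (1.0 - 3.0 * kappa) * psif1  # dW/dI4_1
    w42 = (1.0 - 3.0 * kappa) * psif2

    # inverse of C2
    inv = np.empty_like(C2)
    inv[..., 0, 0] = C2[..., 1, 1] / det
    inv[..., 1, 1] = C2[..., 0, 0] / det
    inv[..., 0, 1] = -C2[..., 0, 1] / det
    inv[..., 1, 0] = -C2[..., 1, 0] / det

    eye = np.zeros_like(C2)
    eye[..., 0, 0] = 1.0
    eye[..., 1, 1] = 1.0

    outer1 = a1[..., :, None] * a1[..., None, :]
    outer2 = a2[..., :, None] * a2[..., None, :]

    S2 = (
        2.0 * w1[..., None, None] * (eye - lam3sq[..., None, None] * inv)
        + 2.0 * w41[..., None, None] * outer1
        + 2.0 * w42[..., None, None] * outer2
    )

    # generous tangent-modulus bound for explicit stability estimates
    stiff = 4.0 * (psi1 + dpsi1) * (1.0 + 3.0 * lam3sq**2) + 4.0 * (
        dpsif1 + dpsif2 + np.abs(psif1) + np.abs(psif2)
    )

    if want_energy:
        w = C10 * (expm - 1.0)
        for E, psif in ((E1, psif1), (E2, psif2)):
            act = psif != 0.0
            w = w + np.where(act, k1 / (2.0 * k2) * (np.exp(np.clip(k2 * E**2, 0, 80)) - 1.0), 0.0)
        return S2, np.sqrt(lam3sq), stiff, w
    return S2, np.sqrt(lam3sq), stiff


def hgo_membrane_stress(state: DeformationState, p: HGOParams):
    """In-plane 2nd Piola-Kirchhoff stress of a membrane point.

    ``state.F`` must map the in-plane reference axes (e1, e2) to the current
    configuration with fibers in-plane; only the upper-left 2x2 in-plane part
    of F is used, the through-thickness stretch is recomputed from J = 1.

    Returns ``(S2 [kPa, 2x2 symmetric], lam3)``; the normal stress is zero by
    construction.
    """
    F2 = state.F[:2, :2]
    C2 = F2.T @ F2
    a1 = state.a01[:2]
    a2 = state.a02[:2]
    n1, n2 = np.linalg.norm(a1), np.linalg.norm(a2)
    if n1 < 1e-8 or n2 < 1e-8:
        raise ValueError("fiber directions must be in-plane for membrane stress")
    fibers = np.stack([a1 / n1, a2 / n2])
    S2, lam3, _ = membrane_response(
        C2[None], fibers[None], p.C10, p.C01, p.k1, p.k2, p.kappa
    )
    return 0.5 * (S2[0] + S2[0].T), float(lam3[0])


def membrane_energy_density(C2: np.ndarray, fibers2d: np.ndarray, p: HGOParams) -> float:
    """Energy density [kPa] of the incompressible membrane at in-plane C2."""
    _, _, _, w = membrane_response(
        np.asarray(C2)[None], np.asarray(fibers2d)[None], p.C10, p.C01, p.k1, p.k2, p.kappa,
        want_energy=True,
    )
    return float(w[0])


def ogden_fiber_tension(lam, p: OgdenParams, ref_area):
    """Axial force [mN] of an incompressible Ogden chord at stretch ``lam``.

    Cauchy stress sigma = sum_i mu_i*(lam^alpha_i - lam^(-alpha_i/2)); the
    force acts on the current cross-section ref_area/lam.  Chords carry no
    compression: the force is clamped at zero for lam <= 1.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be > 0")
    sigma = np.zeros_like(lam)
    for mu, alpha in p.terms:
        sigma = sigma + mu * (lam**alpha - lam ** (-alpha / 2.0))
    force = np.maximum(sigma, 0.0) * np.asarray(ref_area, dtype=float) / lam
    return force if force.ndim else float(force)


def ogden_tangent_stiffness(lam, p: OgdenParams, ref_area, rest_length):
    """Bound on d(force)/d(length) [mN/mm] for solver mass scaling."""
    lam = np.maximum(np.asarray(lam, dtype=float), 1.0)
    dsig = np.zeros_like(lam)
    for mu, alpha in p.terms:
        dsig = dsig + mu * (
            alpha * lam ** (alpha - 1.0) + (alpha / 2.0) * lam ** (-alpha / 2.0 - 1.0)
        )
    return np.abs(dsig) * np.asarray(ref_area) / np.asarray(rest_length)


def load_hgo_params(path: str | Path) -> HGOParams:
    """Read a Holzapfel parameter YAML (fields C10, C01, k1, k2, D, kappa,
    theta_deg, rho)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {"C10", "C01", "k1", "k2", "D", "kappa", "theta_deg", "rho"}
    extra = set(raw) - known - {"description"}
    if extra:
        raise ValueError(f"unknown keys in {path}: {sorted(extra)}")
    raw.pop("description", None)
    return HGOParams(**raw)


def load_ogden_params(path: str | Path) -> OgdenParams:
    """Read an Ogden parameter YAML (list of {mu, alpha} under ``terms``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    terms = tuple((float(t["mu"]), float(t["alpha"])) for t in raw["terms"])
    return OgdenParams(terms=terms, rho=float(raw.get("rho", 1.1)))
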