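"""Numba-fused force kernels for the dynamic-relaxation inner loop.

These mirror the vectorized numpy implementations in :mod:`mvrepair.fe`
exactly (a unit test asserts agreement to machine precision); they exist
only to make the per-step cost of the explicit solver small.  Accumulation
is serial in element order, so results are bit-deterministic.  If numba is
unavailable the solver transparently falls back to the numpy path.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def membrane_forces_kernel(x, tris, Bm, fibers2d, C10, C01, k1, k2, kappa,
                           thickness, A0, out, thr, want_thr,
                           C2out, Fout, S2out, lam3out, stiffout, want_collect):
    m = tris.shape[0]
    for e in range(m):
        i0, i1, i2 = tris[e, 0], tris[e, 1], tris[e, 2]
        d1x = x[i1, 0] - x[i0, 0]
        d1y = x[i1, 1] - x[i0, 1]
        d1z = x[i1, 2] - x[i0, 2]
        d2x = x[i2, 0] - x[i0, 0]
        d2y = x[i2, 1] - x[i0, 1]
        d2z = x[i2, 2] - x[i0, 2]
        b00, b01 = Bm[e, 0, 0], Bm[e, 0, 1]
        b10, b11 = Bm[e, 1, 0], Bm[e, 1, 1]
        # F = Ds @ Bm   (3x2)
        F00 = d1x * b00 + d2x * b10
        F01 = d1x * b01 + d2x * b11
        F10 = d1y * b00 + d2y * b10
        F11 = d1y * b01 + d2y * b11
        F20 = d1z * b00 + d2z * b10
        F21 = d1z * b01 + d2z * b11
        # C2 = F^T F
        c00 = F00 * F00 + F10 * F10 + F20 * F20
        c11 = F01 * F01 + F11 * F11 + F21 * F21
        c01 = F00 * F01 + F10 * F11 + F20 * F21
        det = c00 * c11 - c01 * c01
        if det <= 0.0:
            det = 1e-12
        lam3sq = 1.0 / det
        I1 = c00 + c11 + lam3sq

        a10, a11_ = fibers2d[e, 0, 0], fibers2d[e, 0, 1]
        a20, a21 = fibers2d[e, 1, 0], fibers2d[e, 1, 1]
        I41 = a10 * (c00 * a10 + c01 * a11_) + a11_ * (c01 * a10 + c11 * a11_)
        I42 = a20 * (c00 * a20 + c01 * a21) + a21 * (c01 * a20 + c11 * a21)

        arg = C01[e] * (I1 - 3.0)
        if arg > 80.0:
            arg = 80.0
        elif arg < -80.0:
            arg = -80.0
        expm = np.exp(arg)
        psi1 = C10[e] * C01[e] * expm
        dpsi1 = C10[e] * C01[e] * C01[e] * expm

        E1 = kappa[e] * I1 + (1.0 - 3.0 * kappa[e]) * I41 - 1.0
        if E1 > 0.0:
            g = np.exp(min(k2[e] * E1 * E1, 80.0))
            psif1 = k1[e] * E1 * g
            dpsif1 = k1[e] * g * (1.0 + 2.0 * k2[e] * E1 * E1)
        else:
            psif1 = 0.0
            dpsif1 = 0.0
        E2 = kappa[e] * I1 + (1.0 - 3.0 * kappa[e]) * I42 - 1.0
        if E2 > 0.0:
            g = np.exp(min(k2[e] * E2 * E2, 80.0))
            psif2 = k1[e] * E2 * g
            dpsif2 = k1[e] * g * (1.0 + 2.0 * k2[e] * E2 * E2)
        else:
            psif2 = 0.0
            dpsif2 = 0.0

        w1 = psi1 + kappa[e] * (psif1 + psif2)
        w41 = (1.0 - 3.0 * kappa[e]) * psif1
        w42 = (1.0 - 3.0 * kappa[e]) * psif2

        inv00 = c11 / det
        inv11 = c00 / det
        inv01 = -c01 / det

        S00 = 2.0 * w1 * (1.0 - lam3sq * inv00) + 2.0 * (w41 * a10 * a10 + w42 * a20 * a20)
        S11 = 2.0 * w1 * (1.0 - lam3sq * inv11) + 2.0 * (w41 * a11_ * a11_ + w42 * a21 * a21)
        S01 = 2.0 * w1 * (-lam3sq * inv01) + 2.0 * (w41 * a10 * a11_ + w42 * a20 * a21)

        # P = F S  (3x2)
        P00 = F00 * S00 + F01 * S01
        P01 = F00 * S01 + F01 * S11
        P10 = F10 * S00 + F11 * S01
        P11 = F10 * S01 + F11 * S11
        P20 = F20 * S00 + F21 * S01
        P21 = F20 * S01 + F21 * S11

        at = A0[e] * thickness[e]
        # H = at * P @ Bm^T
        H00 = at * (P00 * b00 + P01 * b01)
        H01 = at * (P00 * b10 + P01 * b11)
        H10 = at * (P10 * b00 + P11 * b01)
        H11 = at * (P10 * b10 + P11 * b11)
        H20 = at * (P20 * b00 + P21 * b01)
        H21 = at * (P20 * b10 + P21 * b11)

        out[i1, 0] -= H00
        out[i1, 1] -= H10
        out[i1, 2] -= H20
        out[i2, 0] -= H01
        out[i2, 1] -= H11
        out[i2, 2] -= H21
        out[i0, 0] += H00 + H01
        out[i0, 1] += H10 + H11
        out[i0, 2] += H20 + H21

        if want_thr:
            g0 = np.sqrt(H00 * H00 + H10 * H10 + H20 * H20)
            g1 = np.sqrt(H01 * H01 + H11 * H11 + H21 * H21)
            thr[i0] += g0 + g1
            thr[i1] += g0 + g1
            thr[i2] += g0 + g1
        if want_collect:
            C2out[e, 0, 0] = c00
            C2out[e, 0, 1] = c01
            C2out[e, 1, 0] = c01
            C2out[e, 1, 1] = c11
            Fout[e, 0, 0] = F00
            Fout[e, 0, 1] = F01
            Fout[e, 1, 0] = F10
            Fout[e, 1, 1] = F11
            Fout[e, 2, 0] = F20
            Fout[e, 2, 1] = F21
            S2out[e, 0, 0] = S00
            S2out[e, 0, 1] = S01
            S2out[e, 1, 0] = S01
            S2out[e, 1, 1] = S11
            lam3out[e] = np.sqrt(lam3sq)
        stiffout[e] = 4.0 * (psi1 + dpsi1) * (1.0 + 3.0 * lam3sq * lam3sq) + 4.0 * (
            dpsif1 + dpsif2 + abs(psif1) + abs(psif2)
        )


@njit(cache=True)
def cable_forces_kernel(x, cables, L0, area, mus, alphas, out, thr, want_thr,
                        lam_out, T_out):
    S = cables.shape[0]
    nt = mus.shape[0]
    for s in range(S):
        a, b = cables[s, 0], cables[s, 1]
        dx = x[b, 0] - x[a, 0]
        dy = x[b, 1] - x[a, 1]
        dz = x[b, 2] - x[a, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        lam = L / L0[s]
        if lam < 1e-9:
            lam = 1e-9
        sig = 0.0
        for t in range(nt):
            sig += mus[t] * (lam ** alphas[t] - lam ** (-alphas[t] / 2.0))
        if sig < 0.0:
            sig = 0.0
        T = sig * area[s] / lam
        lam_out[s] = lam
        T_out[s] = T
        if L > 1e-12:
            ux, uy, uz = dx / L, dy / L, dz / L
            out[a, 0] += T * ux
            out[a, 1] += T * uy
            out[a, 2] += T * uz
            out[b, 0] -= T * ux
            out[b, 1] -= T * uy
            out[b, 2] -= T * uz
            if want_thr:
                thr[a] += T
                thr[b] += T


@njit(cache=True)
def pressure_forces_kernel(x, tris, p, out, thr, want_thr):
    m = tris.shape[0]
    for e in range(m):
        i0, i1, i2 = tris[e, 0], tris[e, 1], tris[e, 2]
        d1x = x[i1, 0] - x[i0, 0]
        d1y = x[i1, 1] - x[i0, 1]
        d1z = x[i1, 2] - x[i0, 2]
        d2x = x[i2, 0] - x[i0, 0]
        d2y = x[i2, 1] - x[i0, 1]
        d2z = x[i2, 2] - x[i0, 2]
        nx = 0.5 * (d1y * d2z - d1z * d2y)
        ny = 0.5 * (d1z * d2x - d1x * d2z)
        nz = 0.5 * (d1x * d2y - d1y * d2x)
        fx = p * nx / 3.0
        fy = p * ny / 3.0
        fz = p * nz / 3.0
        for i in (i0, i1, i2):
            out[i, 0] += fx
            out[i, 1] += fy
            out[i, 2] += fz
        if want_thr:
            g = np.sqrt(fx * fx + fy * fy + fz * fz)
            thr[i0] += g
            thr[i1] += g
            thr[i2] += g
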