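"""Independent literal-transcription oracles for the staggered stencils.

Everything here is written as plain per-pixel loops straight from the
scheme's defining formulas, deliberately sharing no code with the
vectorized implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def o_minmod(m, n):
    return ((np.sign(m) + np.sign(n)) / 2.0) * min(abs(m), abs(n))


def o_pad(a):
    """Neumann mirror ghosts by explicit copying."""
    M, N = a.shape
    p = np.zeros((M + 2, N + 2))
    p[1:-1, 1:-1] = a
    p[0, 1:-1] = a[0]
    p[-1, 1:-1] = a[-1]
    p[:, 0] = p[:, 1]
    p[:, -1] = p[:, -2]
    return p


def o_magnitude(a, h, eps):
    """Whole-pixel ε-regularized magnitude, literal reading (intensity units)."""
    p = o_pad(a)
    M, N = a.shape
    out = np.zeros((M, N))
    for i in range(M):
        for j in range(N):
            dx = p[i + 2, j + 1] - p[i, j + 1]
            dy = p[i + 1, j + 2] - p[i + 1, j]
            out[i, j] = 0.5 * math.sqrt(dx * dx + dy * dy + 4.0 * h * h * eps)
    return out


def o_gradient(a, h):
    """Central-difference per-length gradient with Neumann ghosts."""
    p = o_pad(a)
    M, N = a.shape
    gx = np.zeros((M, N))
    gy = np.zeros((M, N))
    for i in range(M):
        for j in range(N):
            gx[i, j] = (p[i + 2, j + 1] - p[i, j + 1]) / (2 * h)
            gy[i, j] = (p[i + 1, j + 2] - p[i + 1, j]) / (2 * h)
    return gx, gy


def o_curvature(a, h, eps):
    """κ = ∂x(gx/|∇g|ᵣ) + ∂y(gy/|∇g|ᵣ), |∇g|ᵣ = √(gx²+gy²+ε)."""
    gx, gy = o_gradient(a, h)
    mag = np.sqrt(gx * gx + gy * gy + eps)
    nx, ny = gx / mag, gy / mag
    pnx, pny = o_pad(nx), o_pad(ny)
    M, N = a.shape
    k = np.zeros((M, N))
    for i in range(M):
        for j in range(N):
            k[i, j] = (pnx[i + 2, j + 1] - pnx[i, j + 1]) / (2 * h) + (
                pny[i + 1, j + 2] - pny[i + 1, j]
            ) / (2 * h)
    return k


def o_x_face_quantities(a, h, eps, eq40_literal=True):
    """All x-face quantities at (i−½, j), shape (M+1, N), per-face loops."""
    M, N = a.shape
    kappa = o_curvature(a, h, eps)
    mag = o_magnitude(a, h, eps) if eq40_literal else _o_mag_conv(a, h, eps)
    P = kappa * mag
    gp, kp, Pp = o_pad(a), o_pad(kappa), o_pad(P)

    out = {
        q: np.zeros((M + 1, N))
        for q in ("kappa", "d_in", "d_cross", "dP_in", "dP_cross", "magnitude")
    }
    for fi in range(M + 1):  # face between padded rows fi and fi+1
        for j in range(N):
            jc = j + 1
            up, lo = fi + 1, fi
            out["kappa"][fi, j] = o_minmod(kp[up, jc], kp[lo, jc])
            out["d_in"][fi, j] = (gp[up, jc] - gp[lo, jc]) / h
            out["dP_in"][fi, j] = (Pp[up, jc] - Pp[lo, jc]) / h
            cy_up = (gp[up, jc + 1] - gp[up, jc - 1]) / (2 * h)
            cy_lo = (gp[lo, jc + 1] - gp[lo, jc - 1]) / (2 * h)
            out["d_cross"][fi, j] = o_minmod(cy_up, cy_lo)
            cP_up = (Pp[up, jc + 1] - Pp[up, jc - 1]) / (2 * h)
            cP_lo = (Pp[lo, jc + 1] - Pp[lo, jc - 1]) / (2 * h)
            out["dP_cross"][fi, j] = o_minmod(cP_up, cP_lo)
            out["magnitude"][fi, j] = math.sqrt(
                out["d_in"][fi, j] ** 2 + out["d_cross"][fi, j] ** 2 + eps
            )
    return out


def _o_mag_conv(a, h, eps):
    gx, gy = o_gradient(a, h)
    return np.sqrt(gx * gx + gy * gy + eps)


def o_elastica_flux(a, h, eps, a1, a2, eq40_literal=True):
    """(U1, U2) by literal per-face transcription of the flux components.

    Vector form: U = (α₁+α₂κ²)∇g/|∇g| − (2α₂/|∇g|³)·S·∇⊥g with
    S = −g_y·∂x(κ|∇g|) + g_x·∂y(κ|∇g|) and ∇⊥g = (−g_y, g_x); so the first
    component carries −S·(−g_y) = +S·g_y and the second −S·g_x.  Boundary
    faces are zeroed (no normal flux).
    """
    M, N = a.shape
    fx = o_x_face_quantities(a, h, eps, eq40_literal)
    U1 = np.zeros((M + 1, N))
    for fi in range(M + 1):
        for j in range(N):
            gxf = fx["d_in"][fi, j]
            gyf = fx["d_cross"][fi, j]
            mf = fx["magnitude"][fi, j]
            kf = fx["kappa"][fi, j]
            S = -gyf * fx["dP_in"][fi, j] + gxf * fx["dP_cross"][fi, j]
            U1[fi, j] = (a1 + a2 * kf * kf) * gxf / mf + (2 * a2 / mf**3) * S * gyf
    U1[0, :] = 0.0
    U1[-1, :] = 0.0

    fy = o_x_face_quantities(a.T, h, eps, eq40_literal)  # faces of the transpose
    U2 = np.zeros((M, N + 1))
    for fj in range(N + 1):
        for i in range(M):
            gyf = fy["d_in"][fj, i]  # in-axis of transpose = y of original
            gxf = fy["d_cross"][fj, i]
            mf = fy["magnitude"][fj, i]
            kf = fy["kappa"][fj, i]
            # in the transposed frame dP_cross is ∂x(κ|∇g|), dP_in is ∂y(κ|∇g|)
            S = -gyf * fy["dP_cross"][fj, i] + gxf * fy["dP_in"][fj, i]
            U2[i, fj] = (a1 + a2 * kf * kf) * gyf / mf - (2 * a2 / mf**3) * S * gxf
    U2[:, 0] = 0.0
    U2[:, -1] = 0.0
    return U1, U2


def o_divergence(U1, U2, h):
    M, N = U1.shape[0] - 1, U1.shape[1]
    div = np.zeros((M, N))
    for i in range(M):
        for j in range(N):
            div[i, j] = (U1[i + 1, j] - U1[i, j]) / h + (U2[i, j + 1] - U2[i, j]) / h
    return div


def o_energy(g, f, h, eps, b1, b2, a1, a2, eq40_literal=True):
    """Literal per-pixel discrete energy sum."""
    kappa = o_curvature(g, h, eps)
    mag = o_magnitude(g, h, eps) if eq40_literal else _o_mag_conv(g, h, eps)
    M, N = g.shape
    total = 0.0
    for i in range(M):
        for j in range(N):
            reg = (b1 + b2 / g[i, j]) * (a1 + a2 * kappa[i, j] ** 2) * mag[i, j]
            total += reg + math.log(g[i, j]) + f[i, j] / g[i, j]
    return h * h * total


def o_tv_flux(a, h, eps, a1):
    """Pure TV flux: α₁·(in-axis derivative)/face magnitude, zero tangential."""
    fx = o_x_face_quantities(a, h, eps)
    U1 = a1 * fx["d_in"] / fx["magnitude"]
    U1[0, :] = 0.0
    U1[-1, :] = 0.0
    fy = o_x_face_quantities(a.T, h, eps)
    U2 = (a1 * fy["d_in"] / fy["magnitude"]).T
    U2[:, 0] = 0.0
    U2[:, -1] = 0.0
    return U1, U2


def o_psnr(ref, img):
    M, N = ref.shape
    ssd = 0.0
    for i in range(M):
        for j in range(N):
            ssd += (ref[i, j] - img[i, j]) ** 2
    return 10.0 * math.log10(M * N * ref.max() ** 2 / ssd)
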