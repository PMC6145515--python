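"""Discrete differential operators on staggered grids.

Conventions used throughout:

* array axis 0 is the x direction (index i), axis 1 is the y direction
  (index j); Δx = Δy = ``spacing``;
* boundary handling is Neumann via one-pixel mirror ghosts
  (g_{0,j} = g_{1,j} etc.);
* the per-pixel gradient magnitude is the ε-regularized central-difference
  form |∇g|_{i,j} = ½·√((g_{i+1,j}−g_{i−1,j})² + (g_{i,j+1}−g_{i,j−1})²
  + 4Δx²ε).  Taken literally this carries intensity units (no 1/Δx); the
  ``eq40_literal`` switch (default True) keeps that reading, and False uses
  the conventional per-length magnitude √(gx² + gy² + ε);
* half-pixel (face) quantities follow the min-mod staggered scheme: the
  in-axis derivative at a face is the two-point difference of the adjacent
  whole pixels, the cross-axis derivative is the min-mod of the two adjacent
  whole-pixel central differences, and face curvature is the min-mod of the
  two adjacent whole-pixel curvatures.

The min-mod limiter returns zero when its arguments disagree in sign, which
suppresses spurious oscillation when averaging across a face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ImageField

__all__ = [
    "minmod",
    "neumann_pad",
    "central_gradient",
    "curvature",
    "half_pixel_bundle",
    "GradientField",
    "CurvatureField",
    "FaceQuantities",
    "HalfPixelBundle",
]


def minmod(m, n):
    """Min-mod limiter: ((sgn m + sgn n)/2) · min(|m|, |n|).

    Returns the smaller-magnitude argument when both agree in sign and 0
    otherwise.  Works elementwise on arrays.
    """
    m = np.asarray(m, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    out = 0.5 * (np.sign(m) + np.sign(n)) * np.minimum(np.abs(m), np.abs(n))
    if out.ndim == 0:
        return float(out)
    return out


def neumann_pad(values: np.ndarray) -> np.ndarray:
    """One-pixel mirror ghost ring (zero normal derivative).

    Corner ghosts are mirrored in both directions; the order of the two
    reflections does not matter.
    """
    return np.pad(np.asarray(values, dtype=np.float64), 1, mode="edge")


@dataclass
class GradientField:
    """Central-difference gradient with ε-regularized magnitude."""

    gx: np.ndarray  # ∂g/∂x per length unit
    gy: np.ndarray
    magnitude: np.ndarray  # ε-regularized |∇g| (units per eq40_literal)
    epsilon: float
    eq40_literal: bool = True


@dataclass
class CurvatureField:
    """Level-set curvature κ = ∇·(∇g/|∇g|), units 1/length."""

    kappa: np.ndarray


def central_gradient(
    field: ImageField, epsilon: float, eq40_literal: bool = True
) -> GradientField:
    """Whole-pixel gradient by central differences with Neumann ghosts.

    gx, gy are always per-length (divided by 2Δx); the magnitude follows the
    ``eq40_literal`` switch documented in the module docstring.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    h = field.spacing
    gp = neumann_pad(field.values)
    dxr = gp[2:, 1:-1] - gp[:-2, 1:-1]  # g_{i+1,j} - g_{i-1,j}
    dyr = gp[1:-1, 2:] - gp[1:-1, :-2]
    gx = dxr / (2.0 * h)
    gy = dyr / (2.0 * h)
    if eq40_literal:
        mag = 0.5 * np.sqrt(dxr * dxr + dyr * dyr + 4.0 * h * h * epsilon)
    else:
        mag = np.sqrt(gx * gx + gy * gy + epsilon)
    return GradientField(gx, gy, mag, epsilon, eq40_literal)


def curvature(field: ImageField, epsilon: float) -> CurvatureField:
    """Level-set curvature by central differences of the unit normal.

    The unit normal n = ∇g/√(|∇g|² + ε) is dimensionless, so κ is 1/length
    regardless of the magnitude convention.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    h = field.spacing
    g = central_gradient(field, epsilon, eq40_literal=False)
    nx = g.gx / g.magnitude
    ny = g.gy / g.magnitude
    nxp = neumann_pad(nx)
    nyp = neumann_pad(ny)
    kappa = (nxp[2:, 1:-1] - nxp[:-2, 1:-1]) / (2.0 * h) + (
        nyp[1:-1, 2:] - nyp[1:-1, :-2]
    ) / (2.0 * h)
    return CurvatureField(kappa)


@dataclass
class FaceQuantities:
    """Staggered quantities on the faces normal to one axis.

    For the x axis the arrays have shape (M+1, N): entry [i, j] lives at
    (i − ½, j) in 0-based interior indexing, i.e. row 0 and row M are the
    domain-boundary faces.  ``d_in``/``d_cross`` are the in-axis and
    cross-axis derivatives of g, ``dP_in``/``dP_cross`` those of the product
    P = κ·|∇g|, ``kappa`` the min-mod face curvature and ``magnitude`` the
    ε-regularized face gradient magnitude.
    """

    kappa: np.ndarray
    d_in: np.ndarray
    d_cross: np.ndarray
    dP_in: np.ndarray
    dP_cross: np.ndarray
    magnitude: np.ndarray


@dataclass
class HalfPixelBundle:
    """Face quantities for both axes plus the whole-pixel fields they use."""

    x: FaceQuantities
    y: FaceQuantities
    kappa: np.ndarray  # whole-pixel κ, shape (M, N)
    magnitude: np.ndarray  # whole-pixel |∇g| (eq40 convention), shape (M, N)


def _face_quantities(gp, kp, Pp, h, epsilon, axis: int) -> FaceQuantities:
    """Staggered quantities on faces normal to ``axis`` of the padded arrays.

    gp, kp, Pp are Neumann-padded (M+2, N+2) arrays of g, κ and P = κ|∇g|.
    """
    if axis == 1:
        q = _face_quantities(gp.T, kp.T, Pp.T, h, epsilon, axis=0)
        return FaceQuantities(
            q.kappa.T, q.d_in.T, q.d_cross.T, q.dP_in.T, q.dP_cross.T, q.magnitude.T
        )

    # Faces between padded rows r and r+1 for r = 0..M: shape (M+1, N).
    up, lo = (slice(1, None), slice(None, -1))
    c = slice(1, -1)
    kappa = minmod(kp[up, c], kp[lo, c])
    d_in = (gp[up, c] - gp[lo, c]) / h
    dP_in = (Pp[up, c] - Pp[lo, c]) / h
    # Whole-pixel central cross differences, then min-mod across the face.
    cg = (gp[:, 2:] - gp[:, :-2]) / (2.0 * h)  # shape (M+2, N)
    cP = (Pp[:, 2:] - Pp[:, :-2]) / (2.0 * h)
    d_cross = minmod(cg[1:], cg[:-1])
    dP_cross = minmod(cP[1:], cP[:-1])
    magnitude = np.sqrt(d_in * d_in + d_cross * d_cross + epsilon)
    return FaceQuantities(kappa, d_in, d_cross, dP_in, dP_cross, magnitude)


def half_pixel_bundle(
    field: ImageField, epsilon: float, eq40_literal: bool = True
) -> HalfPixelBundle:
    """All staggered quantities the elastica flux assembly consumes.

    Whole-pixel κ and |∇g| are computed first; their Neumann-padded values
    feed the face stencils, which makes the normal flux vanish on the domain
    boundary (zero normal derivative of every padded field).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    h = field.spacing
    kappa = curvature(field, epsilon).kappa
    mag = central_gradient(field, epsilon, eq40_literal=eq40_literal).magnitude
    gp = neumann_pad(field.values)
    kp = neumann_pad(kappa)
    Pp = neumann_pad(kappa * mag)
    fx = _face_quantities(gp, kp, Pp, h, epsilon, axis=0)
    fy = _face_quantities(gp, kp, Pp, h, epsilon, axis=1)
    return HalfPixelBundle(fx, fy, kappa, mag)
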