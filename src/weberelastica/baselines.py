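"""Comparison solvers for multiplicative-noise removal.

Three established variational baselines against which the elastica model is
judged:

* **M1** — Weberized TV with the non-convex Gamma fidelity, solved by
  semi-implicit additive operator splitting (AOS): per time step the
  diffusivity D = 1/(|∇g|² + ε) is frozen, one tridiagonal diffusion system
  is solved per axis, and the two axis solutions are averaged.
* **M3** — hybrid split model on ξ = log f₀ combining a TV-smoothed vector
  field v (Chambolle dual projection), a split-Bregman TV term on ∇ξ (soft
  thresholding + Bregman update) and an exponential fidelity; returns
  exp(ξ).
* **M4** — TV with a non-convex edge indicator b = α/(1 + α|∇ũ|): an outer
  alternation between a weighted-TV + exponential-fidelity problem (inner
  ADMM with a pointwise Newton solve and a weighted Chambolle projection)
  and the edge-indicator update on a Gaussian-smoothed iterate.

M3 and M4 use the forward-difference gradient with backward-difference
(adjoint) divergence and unit grid spacing, the convention the Chambolle
dual relation div = −∇ᵀ requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .elastica import SolverTrace
from .image import ImageField

__all__ = [
    "M1Params",
    "M3Params",
    "M4Params",
    "m1_denoise",
    "soft_threshold",
    "chambolle_v_update",
    "m3_denoise",
    "m4_newton_u",
    "m4_denoise",
]


# ----------------------------------------------------------------------
# shared small pieces
# ----------------------------------------------------------------------

def soft_threshold(x, gamma: float):
    """Soft-thresholding T(x, γ) = (x/|x|)·max(|x| − γ, 0), with T(0) = 0."""
    if gamma <= 0:
        raise ValueError("threshold gamma must be positive")
    x = np.asarray(x, dtype=np.float64)
    out = np.sign(x) * np.maximum(np.abs(x) - gamma, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def _grad_fwd(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with Neumann closure (last difference zero)."""
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:-1, :] = u[1:, :] - u[:-1, :]
    gy[:, :-1] = u[:, 1:] - u[:, :-1]
    return gx, gy


def _div_bwd(px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Backward-difference divergence, the negative adjoint of _grad_fwd."""
    div = np.zeros_like(px)
    div[0, :] = px[0, :]
    div[1:-1, :] = px[1:-1, :] - px[:-2, :]
    div[-1, :] = -px[-2, :]
    dy = np.zeros_like(py)
    dy[:, 0] = py[:, 0]
    dy[:, 1:-1] = py[:, 1:-1] - py[:, :-2]
    dy[:, -1] = -py[:, -2]
    return div + dy


def _psnr_or_none(reference, img):
    from .metrics import psnr

    return None if reference is None else psnr(reference, img)


# ----------------------------------------------------------------------
# M1: Weberized TV via AOS
# ----------------------------------------------------------------------

@dataclass
class M1Params:
    """Weberized-TV AOS solver parameters.

    The diffusivity is D = 1/(|∇g|² + ε) as the model states it
    (``conventional_tv`` switches to the usual 1/√(|∇g|² + ε)).  ``tau`` is
    the AOS time step: diffusion is unconditionally stable, but the
    fidelity term is explicit, so τ·λ̃ must stay below 1 — with the default
    Weber weights and intensities ≳ 10 that allows τ of order 10–100.
    """

    beta1: float = 0.0061
    beta2: float = 0.0411
    epsilon: float = 1e-4
    tau: float = 20.0
    spacing: float = 10.0
    max_iter: int = 300
    rel_tol: float = 1e-6
    positivity_floor: float = 1e-3
    conventional_tv: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.epsilon <= 0:
            raise ValueError("tau and epsilon must be positive")


def _thomas_batch(lower, diag, upper, rhs):
    """Solve a batch of tridiagonal systems, one per column of the inputs.

    All arguments are (n, k) arrays holding k independent systems of size n
    (lower[0] and upper[-1] are ignored).  Plain Thomas elimination,
    vectorized across the batch axis; the systems here are strictly
    diagonally dominant (I − 2τA with A a Neumann diffusion operator), so
    no pivoting is needed.
    """
    n = diag.shape[0]
    c = np.empty_like(diag)
    d = np.empty_like(rhs)
    c[0] = upper[0] / diag[0]
    d[0] = rhs[0] / diag[0]
    for i in range(1, n):
        denom = diag[i] - lower[i] * c[i - 1]
        c[i] = upper[i] / denom if i < n - 1 else 0.0
        d[i] = (rhs[i] - lower[i] * d[i - 1]) / denom
    x = np.empty_like(rhs)
    x[-1] = d[-1]
    for i in range(n - 2, -1, -1):
        x[i] = d[i] - c[i] * x[i + 1]
    return x


def _aos_axis_solve(rhs: np.ndarray, D: np.ndarray, tau: float, h: float) -> np.ndarray:
    """Solve (I − 2τ·A_axis(D))·x = rhs along axis 0 with Neumann closure.

    A uses arithmetic-mean face diffusivities D_{i+½} = (D_i + D_{i+1})/2
    divided by h²; boundary faces carry no flux.
    """
    Dface = 0.5 * (D[1:, :] + D[:-1, :]) / (h * h)  # (n-1, k) interior faces
    n = rhs.shape[0]
    lower = np.zeros_like(rhs)
    upper = np.zeros_like(rhs)
    diag = np.ones_like(rhs)
    lower[1:, :] = -2.0 * tau * Dface
    upper[:-1, :] = -2.0 * tau * Dface
    diag[:-1, :] += 2.0 * tau * Dface
    diag[1:, :] += 2.0 * tau * Dface
    return _thomas_batch(lower, diag, upper, rhs)


def m1_denoise(
    f: ImageField,
    params: M1Params,
    reference: Optional[ImageField] = None,
) -> tuple[ImageField, SolverTrace]:
    """Weberized-TV restoration by additive operator splitting.

    Per step: freeze D = 1/(|∇g|² + ε) at gⁿ, build the explicit-fidelity
    right-hand side gⁿ − τ·λ̃(gⁿ)·(gⁿ − f), solve one tridiagonal system per
    axis with doubled time step, and average the two axis solutions.
    """
    f.require_positive("observed image")
    h = params.spacing
    g = f.values.copy()
    trace = SolverTrace()
    for _ in range(params.max_iter):
        gx = np.zeros_like(g)
        gy = np.zeros_like(g)
        gx[1:-1, :] = (g[2:, :] - g[:-2, :]) / (2 * h)
        gy[:, 1:-1] = (g[:, 2:] - g[:, :-2]) / (2 * h)
        grad2 = gx * gx + gy * gy
        if params.conventional_tv:
            D = 1.0 / np.sqrt(grad2 + params.epsilon)
        else:
            D = 1.0 / (grad2 + params.epsilon)
        lam = params.beta1 + params.beta2 / g
        rhs = g - params.tau * lam * (g - f.values)
        sol_x = _aos_axis_solve(rhs, D, params.tau, h)
        sol_y = _aos_axis_solve(rhs.T, D.T, params.tau, h).T
        g_new = np.maximum(0.5 * (sol_x + sol_y), params.positivity_floor)
        rel = float(np.linalg.norm(g_new - g) / max(np.linalg.norm(g), 1e-300))
        trace.rel_changes.append(rel)
        trace.energies.append(_m1_energy(g_new, f.values, params))
        if reference is not None:
            trace.psnr.append(_psnr_or_none(reference, f.with_values(g_new)))
        g = g_new
        if rel < params.rel_tol:
            break
    return f.with_values(g), trace


def _m1_energy(g: np.ndarray, f: np.ndarray, params: M1Params) -> float:
    h = params.spacing
    gx = np.zeros_like(g)
    gy = np.zeros_like(g)
    gx[1:-1, :] = (g[2:, :] - g[:-2, :]) / (2 * h)
    gy[:, 1:-1] = (g[:, 2:] - g[:, :-2]) / (2 * h)
    tv = np.sqrt(gx * gx + gy * gy + params.epsilon)
    return float(
        h * h * np.sum((params.beta1 + params.beta2 / g) * tv + np.log(g) + f / g)
    )


# ----------------------------------------------------------------------
# M3: hybrid split model (log domain)
# ----------------------------------------------------------------------

@dataclass
class M3Params:
    """Hybrid split-model parameters (log-domain TV + vector-field coupling).

    lam couples the vector field v to ∇ξ, alpha weights TV(∇ξ) through the
    split variable η, beta weights the exponential fidelity, mu is the
    Bregman penalty, tau_dual the Chambolle fixed-point step (≤ 1/8) and
    sigma_prox the proximal-linearized ξ step, which must satisfy
    σ·(β + 8μ) < 2 for stability.
    """

    lam: float = 10.0
    alpha: float = 1.0
    beta: float = 30.0
    mu: float = 10.0
    tau_dual: float = 0.125
    sigma_prox: float = 0.01
    n_dual: int = 10
    max_iter: int = 120
    rel_tol: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("lam", "alpha", "beta", "mu", "tau_dual", "sigma_prox"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def chambolle_v_update(xi: np.ndarray, params: M3Params) -> tuple[np.ndarray, np.ndarray]:
    """TV-smooth the gradient of ξ by Chambolle's dual projection.

    Solves, componentwise for w = ∂ξ/∂x and ∂ξ/∂y,
    min_v TV(v) + (λ/2)‖v − w‖² via the dual fixed point
    p ← (p + τ∇(div p − λw)) / (1 + τ|∇(div p − λw)|), p⁰ = 0,
    and returns v = w − (1/λ)·div p for each component.  The normalized
    update keeps |p| ≤ 1 in each sweep.
    """
    w1, w2 = _grad_fwd(xi)
    out = []
    for w in (w1, w2):
        px = np.zeros_like(w)
        py = np.zeros_like(w)
        for _ in range(params.n_dual):
            r = _div_bwd(px, py) - params.lam * w
            rx, ry = _grad_fwd(r)
            mag = np.sqrt(rx * rx + ry * ry)
            px = (px + params.tau_dual * rx) / (1.0 + params.tau_dual * mag)
            py = (py + params.tau_dual * ry) / (1.0 + params.tau_dual * mag)
        out.append(w - _div_bwd(px, py) / params.lam)
    return out[0], out[1]


def m3_denoise(
    f0: ImageField,
    params: M3Params,
    reference: Optional[ImageField] = None,
) -> tuple[ImageField, SolverTrace]:
    """Hybrid split restoration: alternate v, ξ, η and Bregman updates.

    Works on ξ = log f₀ (so the output exp(ξ) is strictly positive):
    v by Chambolle projection of ∇ξ; ξ by one proximal-linearized step
    ξ ← ξ − σ[β(1 − f₀e^{−ξ}) − μ·div(∇ξ − η + b)]; η by soft thresholding
    of (λv + μ(∇ξ − b))/(λ + μ) at α/(λ + μ); b ← b + η − ∇ξ.
    """
    f0.require_positive("observed image")
    z = f0.values
    xi = np.log(z)
    eta1 = np.zeros_like(xi)
    eta2 = np.zeros_like(xi)
    b1 = np.zeros_like(xi)
    b2 = np.zeros_like(xi)
    trace = SolverTrace()
    for _ in range(params.max_iter):
        v1, v2 = chambolle_v_update(xi, params)
        gx, gy = _grad_fwd(xi)
        grad_fid = params.beta * (1.0 - z * np.exp(-xi))
        # Gradient of (μ/2)||η − ∇ξ + b||² is −μ·div(∇ξ − η − b); the "+b"
        # variant breaks the Bregman feedback and drifts monotonically.
        xi_new = xi - params.sigma_prox * (
            grad_fid - params.mu * _div_bwd(gx - eta1 - b1, gy - eta2 - b2)
        )
        gxn, gyn = _grad_fwd(xi_new)
        denom = params.lam + params.mu
        eta1 = soft_threshold(
            (params.lam * v1 + params.mu * (gxn - b1)) / denom, params.alpha / denom
        )
        eta2 = soft_threshold(
            (params.lam * v2 + params.mu * (gyn - b2)) / denom, params.alpha / denom
        )
        b1 = b1 + eta1 - gxn
        b2 = b2 + eta2 - gyn
        rel = float(np.linalg.norm(xi_new - xi) / max(np.linalg.norm(xi), 1e-300))
        trace.rel_changes.append(rel)
        trace.energies.append(_m3_energy(xi_new, v1, v2, z, params))
        if reference is not None:
            trace.psnr.append(_psnr_or_none(reference, f0.with_values(np.exp(xi_new))))
        xi = xi_new
        if rel < params.rel_tol:
            break
    return f0.with_values(np.exp(xi)), trace


def _m3_energy(xi, v1, v2, z, params: M3Params) -> float:
    gx, gy = _grad_fwd(xi)
    v1x, v1y = _grad_fwd(v1)
    v2x, v2y = _grad_fwd(v2)
    tv_v = np.sqrt(v1x**2 + v1y**2) + np.sqrt(v2x**2 + v2y**2)
    coupling = 0.5 * params.lam * ((gx - v1) ** 2 + (gy - v2) ** 2)
    tv_xi = np.sqrt(gx * gx + gy * gy)
    fid = z * np.exp(-xi) + xi
    return float(np.sum(tv_v + coupling + params.alpha * tv_xi + params.beta * fid))


# ----------------------------------------------------------------------
# M4: TV + nonconvex edge indicator via ADMM
# ----------------------------------------------------------------------

@dataclass
class M4Params:
    """Weighted-TV + edge-indicator solver parameters.

    The edge indicator b = α/(1 + α|∇ũ|) ∈ (0, α] gates the TV weight
    ϵ + (1−ϵ)b²: large in flat regions (strong smoothing), small across
    edges.  ũ is the inner solution convolved with a Gaussian of width
    sigma_smooth.  rho_dual is the weighted Chambolle projection step and
    tau_stop the mean-change outer stopping threshold.
    """

    lam: float = 20.0
    eps_cvx: float = 0.1
    alpha_b: float = 10.0
    sigma_smooth: float = 1.5
    mu: float = 10.0
    rho_dual: float = 0.125
    tau_stop: float = 1e-4
    newton_iters: int = 5
    n_dual: int = 10
    inner_iters: int = 5
    outer_iters: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.eps_cvx < 1:
            raise ValueError("eps_cvx must lie in (0, 1)")
        if self.alpha_b <= 0 or self.lam <= 0 or self.mu <= 0:
            raise ValueError("alpha_b, lam and mu must be positive")


def m4_newton_u(
    v: np.ndarray,
    d: np.ndarray,
    z: np.ndarray,
    lam: float,
    mu: float,
    iters: int = 5,
) -> np.ndarray:
    """Pointwise Newton solve of λ(1 − z·e^{−u}) + μ(u − v + d) = 0.

    φ′(u) = λz·e^{−u} + μ > 0, so the root is unique; a handful of Newton
    steps from u = v − d converges to round-off.
    """
    if np.any(z <= 0):
        raise ValueError("z must be strictly positive")
    u = v - d
    for _ in range(iters):
        e = z * np.exp(-u)
        phi = lam * (1.0 - e) + mu * (u - v + d)
        u = u - phi / (lam * e + mu)
    return u


def _weighted_chambolle_v(target: np.ndarray, weight: np.ndarray, params: M4Params) -> np.ndarray:
    """Weighted-TV proximal of ``target`` via the projection q, |q| ≤ weight.

    Solves min_v (μ/2)‖target − v‖² + ∫ weight·|∇v| and returns
    v = target − (λ/μ)·div q with q from the normalized fixed point.
    """
    qx = np.zeros_like(target)
    qy = np.zeros_like(target)
    scale = params.mu / params.lam
    for _ in range(params.n_dual):
        r = _div_bwd(qx, qy) - scale * target
        rx, ry = _grad_fwd(r)
        mag = np.sqrt(rx * rx + ry * ry)
        denom = 1.0 + params.rho_dual * mag / np.maximum(weight, 1e-12)
        qx = (qx + params.rho_dual * rx) / denom
        qy = (qy + params.rho_dual * ry) / denom
    return target - (params.lam / params.mu) * _div_bwd(qx, qy)


def m4_denoise(
    z: ImageField,
    params: M4Params,
    reference: Optional[ImageField] = None,
) -> tuple[ImageField, SolverTrace]:
    """TV + nonconvex edge-indicator restoration of multiplicative noise.

    Outer loop: solve the weighted-TV subproblem in u = log(intensity) by
    inner ADMM (Newton u-update, weighted Chambolle v-update, dual update
    d += u − v), smooth ũ = Gaussian(u, σ), refresh b = α/(1 + α|∇ũ|);
    stop when the mean absolute change of u falls below tau_stop.
    Returns exp(u), hence a strictly positive image.
    """
    z.require_positive("observed image")
    zv = z.values
    u = np.log(zv)
    b = np.full_like(u, params.alpha_b)
    trace = SolverTrace()
    for _ in range(params.outer_iters):
        weight = params.eps_cvx + (1.0 - params.eps_cvx) * b * b
        u_outer_prev = u
        v = u.copy()
        d = np.zeros_like(u)
        for _ in range(params.inner_iters):
            u = m4_newton_u(v, d, zv, params.lam, params.mu, params.newton_iters)
            v = _weighted_chambolle_v(u + d, weight, params)
            d = d + (u - v)
        u_smooth = gaussian_filter(u, params.sigma_smooth, mode="nearest")
        gx, gy = _grad_fwd(u_smooth)
        b = params.alpha_b / (1.0 + params.alpha_b * np.sqrt(gx * gx + gy * gy))
        mean_change = float(np.mean(np.abs(u - u_outer_prev)))
        rel = float(np.linalg.norm(u - u_outer_prev) / max(np.linalg.norm(u), 1e-300))
        trace.rel_changes.append(rel)
        trace.energies.append(_m4_energy(u, b, zv, params))
        if reference is not None:
            trace.psnr.append(_psnr_or_none(reference, z.with_values(np.exp(u))))
        if mean_change < params.tau_stop:
            break
    return z.with_values(np.exp(u)), trace


def _m4_energy(u, b, z, params: M4Params) -> float:
    gx, gy = _grad_fwd(u)
    tv = (params.eps_cvx + (1 - params.eps_cvx) * b * b) * np.sqrt(gx * gx + gy * gy)
    fid = params.lam * (u + z * np.exp(-u))
    shape_term = (1 - params.eps_cvx) * (1.0 - b / params.alpha_b)
    return float(np.sum(fid + tv + shape_term))
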