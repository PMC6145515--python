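"""M1 (AOS), M3 (hybrid split), M4 (edge-indicator ADMM) solver checks."""

import numpy as np
import pytest

from weberelastica import (
    ImageField,
    M1Params,
    M3Params,
    M4Params,
    chambolle_v_update,
    default_shapes_phantom,
    m1_denoise,
    m3_denoise,
    m4_denoise,
    m4_newton_u,
    psnr,
    soft_threshold,
    speckle_gamma,
    speckle_uniform,
)
from weberelastica.baselines import _aos_axis_solve, _div_bwd, _grad_fwd


@pytest.mark.parametrize(
    "x, gamma, expected",
    [(5.0, 2.0, 3.0), (1.0, 2.0, 0.0), (-5.0, 2.0, -3.0), (0.0, 1.0, 0.0), (2.0, 2.0, 0.0)],
)
def test_soft_threshold_truth_table(x, gamma, expected):
    assert soft_threshold(x, gamma) == expected


def test_soft_threshold_rejects_bad_gamma():
    with pytest.raises(ValueError):
        soft_threshold(1.0, 0.0)


def test_grad_div_adjointness(rng):
    """⟨∇u, p⟩ = −⟨u, div p⟩: the duality the Chambolle scheme requires."""
    u = rng.normal(size=(7, 6))
    px = rng.normal(size=(7, 6))
    py = rng.normal(size=(7, 6))
    gx, gy = _grad_fwd(u)
    lhs = np.sum(gx * px + gy * py)
    rhs = -np.sum(u * _div_bwd(px, py))
    assert lhs == pytest.approx(rhs, rel=1e-12)


class TestM1:
    def test_constant_fixed_point(self):
        f = ImageField(np.full((8, 8), 60.0), spacing=1.0)
        out, _ = m1_denoise(f, M1Params(spacing=1.0, max_iter=5))
        assert np.allclose(out.values, 60.0)

    def test_aos_matches_unsplit_solve_as_tau_shrinks(self, rng):
        """The AOS splitting error versus the directly assembled 2-D
        semi-implicit solve is O(τ²): halving τ shrinks the error ~4×."""
        from scipy.sparse import eye, diags, kron, identity
        from scipy.sparse.linalg import spsolve

        n = 16
        a = rng.uniform(10.0, 200.0, size=(n, n))
        D = rng.uniform(0.5, 2.0, size=(n, n))
        rhs = a.copy()

        def unsplit(tau):
            # assemble (I - tau*(Ax+Ay)) on the full grid
            idx = np.arange(n * n).reshape(n, n)
            rows, cols, vals = [], [], []
            for axis in (0, 1):
                for i in range(n):
                    for j in range(n):
                        for d in (-1, 1):
                            ii, jj = (i + d, j) if axis == 0 else (i, j + d)
                            if 0 <= ii < n and 0 <= jj < n:
                                Df = 0.5 * (D[i, j] + D[ii, jj])
                                rows += [idx[i, j], idx[i, j]]
                                cols += [idx[ii, jj], idx[i, j]]
                                vals += [-tau * Df, tau * Df]
            from scipy.sparse import coo_matrix

            A = coo_matrix((vals, (rows, cols)), shape=(n * n, n * n)).tocsr()
            A = A + identity(n * n)
            return spsolve(A, rhs.ravel()).reshape(n, n)

        def aos(tau):
            # ½[(I−2τAx)⁻¹ + (I−2τAy)⁻¹] approximates (I−τ(Ax+Ay))⁻¹
            sx = _aos_axis_solve(rhs, D, tau, 1.0)
            sy = _aos_axis_solve(rhs.T, D.T, tau, 1.0).T
            return 0.5 * (sx + sy)

        errs = [np.linalg.norm(aos(tau) - unsplit(tau)) for tau in (0.01, 0.005)]
        assert errs[1] < errs[0] / 3.0  # halving τ shrinks the gap ≈4×: O(τ²)

    def test_max_principle_without_fidelity(self, rng):
        """Pure AOS diffusion keeps the output range inside the input range."""
        a = rng.uniform(10.0, 200.0, size=(12, 12))
        f = ImageField(a, spacing=1.0)
        p = M1Params(beta1=0.0, beta2=1e-12, spacing=1.0, tau=50.0, max_iter=20)
        out, _ = m1_denoise(f, p)
        assert out.values.min() >= a.min() - 1e-8
        assert out.values.max() <= a.max() + 1e-8

    def test_denoising_improves_psnr(self):
        clean = default_shapes_phantom(64, spacing=1.0)
        for seed in range(5):
            noisy = speckle_uniform(clean, 0.1, seed=seed)
            out, _ = m1_denoise(noisy, M1Params(spacing=1.0))
            assert psnr(clean, out) > psnr(clean, noisy)


class TestChambolle:
    def test_constant_input_zero_field(self):
        v1, v2 = chambolle_v_update(np.full((8, 8), 3.0), M3Params())
        assert np.allclose(v1, 0.0) and np.allclose(v2, 0.0)

    def test_large_lambda_returns_gradient(self):
        """As λ → ∞ the TV proximal map degenerates to the identity."""
        x = np.add.outer(np.linspace(0, 5, 10), np.linspace(0, 3, 10))
        p = M3Params(lam=1e8, n_dual=30)
        v1, v2 = chambolle_v_update(x, p)
        gx, gy = _grad_fwd(x)
        assert np.allclose(v1, gx, atol=1e-5)
        assert np.allclose(v2, gy, atol=1e-5)

    def test_dual_variables_stay_bounded(self, rng):
        """The normalized update keeps the dual magnitude ≤ 1 + O(τ)."""
        xi = rng.normal(size=(10, 10)) * 3
        # re-run the inner iteration manually to inspect p
        from weberelastica.baselines import _grad_fwd as gf, _div_bwd as db

        params = M3Params(n_dual=25)
        w = gf(xi)[0]
        px = np.zeros_like(w)
        py = np.zeros_like(w)
        for _ in range(params.n_dual):
            r = db(px, py) - params.lam * w
            rx, ry = gf(r)
            mag = np.sqrt(rx**2 + ry**2)
            px = (px + params.tau_dual * rx) / (1.0 + params.tau_dual * mag)
            py = (py + params.tau_dual * ry) / (1.0 + params.tau_dual * mag)
            assert np.sqrt(px**2 + py**2).max() <= 1.0 + params.tau_dual + 1e-9


class TestM3:
    def test_constant_fixed_point(self):
        f = ImageField(np.full((8, 8), 40.0), spacing=1.0)
        out, _ = m3_denoise(f, M3Params(max_iter=10))
        assert np.allclose(out.values, 40.0, rtol=1e-10)

    def test_output_strictly_positive(self):
        clean = default_shapes_phantom(32, spacing=1.0)
        noisy = speckle_gamma(clean, 3.0, seed=1)
        out, _ = m3_denoise(noisy, M3Params(max_iter=30))
        assert out.is_positive()

    def test_denoising_improves_psnr_gamma_noise(self):
        clean = default_shapes_phantom(64, spacing=1.0)
        for seed in range(5):
            noisy = speckle_gamma(clean, 3.0, seed=seed)
            out, _ = m3_denoise(noisy, M3Params())
            assert psnr(clean, out) > psnr(clean, noisy)

    def test_eta_update_matches_literal_transcription(self, rng):
        """η = T((λv + μ(∇ξ − b))/(λ+μ), α/(λ+μ)) elementwise."""
        p = M3Params()
        v = rng.normal(size=(6, 6))
        gx = rng.normal(size=(6, 6))
        b = rng.normal(size=(6, 6))
        arg = (p.lam * v + p.mu * (gx - b)) / (p.lam + p.mu)
        ours = soft_threshold(arg, p.alpha / (p.lam + p.mu))
        # literal: (1/(λ+μ))·T(λv + μ(∇ξ−b), α) with T(x,γ)=x/|x|·max(|x|−γ,0)
        x = p.lam * v + p.mu * (gx - b)
        lit = np.where(
            np.abs(x) > 0, np.sign(x) * np.maximum(np.abs(x) - p.alpha, 0.0), 0.0
        ) / (p.lam + p.mu)
        assert np.allclose(ours, lit, atol=1e-12)


class TestM4:
    def test_newton_exact_root_case(self):
        """At v − d = log z both terms vanish: the root is exactly log z."""
        z = np.full((4, 4), 7.0)
        u = m4_newton_u(np.log(z), np.zeros_like(z), z, 20.0, 10.0)
        assert np.allclose(u, np.log(7.0), atol=1e-14)

    def test_newton_residual_tiny(self, rng):
        """In the regime the ADMM visits (init within ~1 of the root) five
        Newton steps reach round-off residuals."""
        z = rng.uniform(1.0, 200.0, size=(8, 8))
        v = np.log(z) + 0.3 * rng.normal(size=(8, 8))
        d = 0.1 * rng.normal(size=(8, 8))
        lam, mu = 20.0, 10.0
        u = m4_newton_u(v, d, z, lam, mu, iters=5)
        resid = lam * (1 - z * np.exp(-u)) + mu * (u - v + d)
        assert np.abs(resid).max() < 1e-10

    def test_newton_penalty_dominates(self):
        z = np.full((3, 3), 5.0)
        v = np.full((3, 3), 2.0)
        d = np.full((3, 3), 0.5)
        u = m4_newton_u(v, d, z, 1.0, 1e8, iters=10)
        assert np.allclose(u, 1.5, atol=1e-6)

    def test_constant_fixed_point(self):
        f = ImageField(np.full((8, 8), 25.0), spacing=1.0)
        out, _ = m4_denoise(f, M4Params(outer_iters=3))
        assert np.allclose(out.values, 25.0, rtol=1e-8)

    def test_edge_indicator_range(self):
        clean = default_shapes_phantom(32, spacing=1.0)
        noisy = speckle_gamma(clean, 3.0, seed=2)
        p = M4Params(outer_iters=3)
        # run and inspect b through the returned trace energies being finite;
        # recompute b as the solver does for the final iterate
        out, _ = m4_denoise(noisy, p)
        from scipy.ndimage import gaussian_filter

        u = np.log(out.values)
        us = gaussian_filter(u, p.sigma_smooth, mode="nearest")
        gx, gy = _grad_fwd(us)
        b = p.alpha_b / (1.0 + p.alpha_b * np.hypot(gx, gy))
        assert b.max() <= p.alpha_b + 1e-12 and b.min() > 0

    def test_denoising_improves_psnr_gamma_noise(self):
        clean = default_shapes_phantom(64, spacing=1.0)
        for seed in range(5):
            noisy = speckle_gamma(clean, 3.0, seed=seed)
            out, _ = m4_denoise(noisy, M4Params())
            assert psnr(clean, out) > psnr(clean, noisy)

    def test_inner_admm_descends_augmented_objective(self):
        """The inner ADMM decreases the weighted-TV + fidelity objective
        over its first iterations on a seeded phantom."""
        clean = default_shapes_phantom(32, spacing=1.0)
        noisy = speckle_gamma(clean, 3.0, seed=3)
        p = M4Params()
        zv = noisy.values
        u = np.log(zv)
        b = np.full_like(u, p.alpha_b)
        weight = p.eps_cvx + (1 - p.eps_cvx) * b * b
        from weberelastica.baselines import _weighted_chambolle_v

        def objective(u):
            gx, gy = _grad_fwd(u)
            return float(
                np.sum(p.lam * (u + zv * np.exp(-u)) + weight * np.hypot(gx, gy))
            )

        v = u.copy()
        d = np.zeros_like(u)
        vals = [objective(u)]
        for _ in range(10):
            u = m4_newton_u(v, d, zv, p.lam, p.mu, p.newton_iters)
            v = _weighted_chambolle_v(u + d, weight, p)
            d = d + (u - v)
            vals.append(objective(v))
        assert vals[-1] <= vals[0] * (1 + 1e-9)
        assert min(vals) < vals[0]
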