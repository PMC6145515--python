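# Methods

## The restoration model

The package removes multiplicative (speckle) noise, f = g·η with E[η] = 1,
from strictly positive 2-D images.  The core solver (called **M2**
throughout the code, after its position in the comparison set) minimizes

    E(g) = ∬ (β₁ + β₂/g)·(α₁ + α₂κ²)·|∇g| dx dy + ∬ (log g + f/g) dx dy,

where κ = ∇·(∇g/|∇g|) is the curvature of the iso-intensity contours.  The
regularizer is Euler's elastica — length plus squared curvature of every
level line, via the co-area formula — modulated by the Weber factor
(β₁ + β₂/g), which penalizes *relative* rather than absolute local contrast
(Weber's law of perception: a given increment is less visible on a bright
background).  The data term log g + f/g is the Gamma-MAP fidelity for
multiplicative noise; it is minimized at g = f pointwise and grows only
logarithmically for over-estimates, matching the skewness of speckle.

The first variation yields the fourth-order Euler–Lagrange equation
−∇·U + λ̃(g)(g − f) = 0 with λ̃ = β₁ + β₂/g and

    U = (α₁ + α₂κ²)·∇g/|∇g| − (2α₂/|∇g|³)·(∇⊥g·∇(κ|∇g|))·∇⊥g,
    ∇⊥g = (−g_y, g_x).

Both flux components are derived from this vector form.  (The
component-wise expansion that circulates in the literature carries an
inconsistent sign on the tangential part of the first component; deriving
both components from the vector form restores exact equivariance under 90°
rotations and axis flips, which the test suite verifies to 1e-8.)

The equation is integrated by explicit ("gradient descent") time stepping

    gⁿ⁺¹ = gⁿ + dt·[∇·U(gⁿ) − λ̃(gⁿ)(gⁿ − f)],   g⁰ = f,

with the fidelity entering with the minus sign: descent of E.  (A
`verbatim_sign` debug switch implements the "+" variant sometimes printed
with this scheme; it ascends the fidelity term and cannot converge to f in
the pure-fidelity limit, so it is never the default.)  Iterates are clamped
to a small positivity floor; clamp events are counted on the solver trace.

## Discretization

Min-mod staggered finite differences with Neumann (mirror-ghost) boundary
conditions:

* whole-pixel magnitude |∇g|_{ij} = ½√((g_{i+1,j}−g_{i−1,j})² +
  (g_{i,j+1}−g_{i,j−1})² + 4Δx²ε).  Read literally this quantity carries
  intensity units (no 1/Δx); the `eq40_literal` switch (default on) keeps
  the literal reading, the alternative is the conventional per-length
  magnitude √(gx² + gy² + ε).
* whole-pixel curvature: central differences of the ε-regularized unit
  normal — the standard level-set stencil; the unit normal is the same
  under either magnitude convention.
* face (half-pixel) quantities: in-axis derivatives by two-point
  differences; cross-axis derivatives by the min-mod limiter of the two
  adjacent whole-pixel central differences (a uniform 1/(2Δy) divisor is
  applied to all min-mod central differences); face curvature by min-mod of
  the two adjacent whole-pixel curvatures; face magnitude
  √(in² + cross² + ε).  Min-mod returns zero when its arguments disagree in
  sign, which suppresses oscillations at extrema.
* divergence: two-point face differences; boundary faces carry zero flux,
  so the discrete divergence theorem (domain sum = 0) holds to round-off.

The flux assembly is verified against an independent per-face loop
transcription of the defining formulas on random fields to 1e-12.

### Time step, grid spacing and the benchmark configuration

`ElasticaParams` defaults to Δx = Δy = 10 and dt = 2×10⁻⁴, the classical
reported configuration for the tuned per-image presets.  That pairing,
however, places the explicit scheme roughly four orders of magnitude below
its stability limit: with Δx = 10 every discrete derivative shrinks by 10
and the divergence by another 10, so at dt = 2×10⁻⁴ the flow moves
intensities by ~10⁻⁵ gray levels per iteration and is computationally inert
at any feasible iteration count.  The package's own phantom benchmark
therefore runs in **pixel units** (Δx = Δy = 1), where the fourth-order
term makes the scheme genuinely stiff: the explicit update destabilizes
between dt ≈ 0.1 and 0.2 on the benchmark phantom, and the
convergence-optimal step is dt ≈ 0.02, used with a 3000-iteration budget
(a 128² run takes a few seconds).  This reproduces the qualitative
time-step phenomenology of this family of schemes: a somewhat smaller dt
under the same budget under-converges slightly, 10× larger degrades the
restoration, 100× larger destroys it.

ε defaults to 10⁻⁴ (intensity-squared units): small enough not to bias the
cone-phantom curvature test (κ within 5% of 1/r), large enough to keep
1/|∇g|³ bounded in flat regions.

### Parameters of the benchmark preset

The classical tuning ranges at σ² = 0.1 are β₁ ∈ [0.0025, 0.0097],
β₂ ∈ [0.0082, 0.074], α₁ ∈ [0.29, 0.50], α₂ ∈ [1.22, 1.61]; their midpoint
is the `generic` preset, and the per-image quadruples for the classic test
images (Moon, Rose, …) ship as named presets.  Those values set the
regularizer-to-fidelity balance at Δx = 10; in pixel units the balance
shifts by the same factor of 10, so the benchmark quadruple was re-tuned by
the same procedure used per image classically: a coarse joint-scale search
on the 128² shapes phantom at σ² = 0.1 (three development seeds disjoint
from the evaluation seeds, mean PSNR over seeds).  The joint scale peaked
at 2.5× the midpoint, giving the frozen `shapes128` preset
(β₁, β₂, α₁, α₂) = (0.01525, 0.10275, 0.9875, 3.5375).  PSNR there is
~29.8 dB versus ~17.9 dB noisy; scaling the quadruple jointly by 0.3, 0.6,
1.4 or 1.7 lowers PSNR on every development seed, which is what the
sensitivity harness then demonstrates on fresh seeds.

## Comparison solvers

* **M1, Weberized TV via AOS.**  ∂g/∂t = div(∇g/(|∇g|² + ε)) − λ̃(g − f)
  with the same λ̃.  The squared-magnitude diffusivity denominator is kept
  as the model states it (`conventional_tv` restores 1/√(|∇g|²+ε)).  Each
  step freezes D = 1/(|∇g|²+ε), forms the explicit-fidelity right-hand
  side, solves one tridiagonal system (I − 2τA_axis(D)) per axis with
  arithmetic face diffusivities and averages the two axis solutions —
  additive operator splitting, unconditionally stable for the diffusion
  part; the explicit fidelity bounds τ·λ̃ ≲ 1, hence the default τ = 20 for
  intensities ≳ 10.  The axis systems (one per image column, all
  different) are solved by a batched Thomas elimination; the matrices are
  strictly diagonally dominant, so no pivoting is needed.
* **M3, hybrid split model.**  Works on ξ = log f₀: a Chambolle dual
  projection TV-smooths each component of ∇ξ into a vector field v; ξ takes
  one proximal-linearized step on the exponential fidelity plus the penalty
  μ/2‖η − ∇ξ + b‖²; the split variable η is a soft threshold at α/(λ+μ);
  b is the Bregman accumulator.  Two numerical notes: (i) the ξ-step uses
  −b inside the divergence, the sign the penalty's gradient actually has —
  the "+b" variant breaks the Bregman feedback and drifts monotonically
  away from the data; (ii) the proximal step must satisfy σ(β + 8μ) < 2,
  so σ defaults to 0.01 with β = 30, μ = 10.
* **M4, TV with a non-convex edge indicator.**  u = log z; outer loop
  alternates a weighted-TV + exponential-fidelity subproblem with the edge
  indicator b = α/(1 + α|∇ũ|) ∈ (0, α], computed on a Gaussian-smoothed ũ
  (normalized kernel of width σ, which makes the smoother exact on
  constants).  The subproblem runs a few ADMM sweeps: a pointwise Newton
  solve of λ(1 − z e^{−u}) + μ(u − v + d) = 0 (strictly monotone, unique
  root, initialized at v − d), a weighted Chambolle projection with
  pointwise dual constraint |q| ≤ ϵ + (1−ϵ)b², and the scaled dual update.

M3/M4 gradients are forward differences with the backward-difference
adjoint divergence (div = −∇ᵀ, required by the dual projections) at unit
spacing.  Their weights (λ = 10, α = 1, β = 30, μ = 10 for M3; λ = 20,
ϵ = 0.1, α = 10, σ = 1.5, μ = 10, ϱ = 1/8 for M4) are stock values for
log-domain TV models on 8-bit-range data; the experiment harness only
relies on their qualitative behaviour (they improve PSNR and all four
solvers fix constant images exactly), never on the exact numbers.

## Noise simulator

Uniform speckle with mean 1 and variance σ² is Uniform[1 − √(3σ²),
1 + √(3σ²)] — the unique uniform law with those two moments; σ² < 1/3 keeps
the support positive.  Gamma speckle is the L-look intensity model
Gamma(shape L, scale 1/L), mean 1, variance 1/L.  Both are driven by
`numpy.random.default_rng(seed)` and are bit-reproducible per seed.

## Phantoms and what the synthetic benchmark does not show

Three deterministic phantom classes: piecewise-constant shapes (edges,
the primary benchmark), linear ramps (staircase behaviour), periodic
sin×sin textures (texture preservation).  The benchmark phantom is 128²
with a disk, a rectangle and a small bright disk (intensities 50–240,
floor 1).  Synthetic phantoms have exactly piecewise-constant/smooth
structure, uncorrelated noise and known ground truth; results on them do
not bound performance on natural images (mixed textures, correlated
speckle, unknown ground truth), and the classical per-image PSNR tables
for Moon/Lena/etc. are not reproducible without those exact images and
noise realizations — the harness instead tests the *directional* claims
(elastica beats plain Weber-TV; the tuned dt and the tuned quadruple are
local optima) as multi-seed stochastic properties.

## Numerical edge cases

* Solver inputs must be strictly positive; loaders shift 8-bit data to
  [floor, floor + 255], floor = 1 by default (the model divides by g and
  takes log g).
* Constant fields: flux, curvature and all face derivatives vanish
  identically, so every solver fixes them exactly (tested).
* PSNR of identical images reports +inf; the reference argument's peak
  sets the signal level, so the argument order is part of the contract.
* If the explicit M2 update produces a non-finite value the solver stops,
  flags the trace as diverged and returns the last finite iterate.

## Known limitations

* M2 is the plain explicit scheme; no operator splitting or augmented
  Lagrangian acceleration (out of scope here), so it needs thousands of
  iterations near its stability limit.
* The min-mod scheme is first-order; no WENO/upwind variants.
* Only uncorrelated single-look-per-pixel noise; no spatially correlated
  speckle.
* SSIM or perceptual metrics are not implemented; PSNR and line profiles
  only.
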