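# Methods

## The reconstruction problem

2D parallel-beam CT measures line integrals of an attenuation map
`u ∈ R^{n_x × n_y}`. Discretizing both image and detector gives the linear
model `g = A u`, with `g ∈ R^{n_p × n_a}` the sinogram (detector bins ×
view angles) and `A` the system matrix. With few views the system is
underdetermined, so reconstruction is posed as a convex program built
around the isotropic total variation

    TV(u) = Σ_{x,y} sqrt( (u_{x,y} − u_{x−1,y})² + (u_{x,y} − u_{x,y−1})² ),

using backward differences that are zero on the first row/column. Three
standard TV models are supported:

| model | program |
|-------|---------|
| ucTV  | min ½‖Au − g‖² + α·TV(u) |
| DDcTV | min TV(u)  s.t. ‖Au − g‖₂ ≤ ε |
| TVcDM | min ½‖Au − g‖²  s.t. TV(u) ≤ t |

## The fully linearized ADMM solver

Each model is split with auxiliaries (`y = Du`, and `z = Au − g` for
DDcTV) and solved by ADMM on the augmented Lagrangian with penalty β (β₁,
β₂ for the two DDcTV splits). The image sub-problem couples `AᵀA` and
`DᵀD` and has no closed form for a general system matrix. The scheme used
here linearizes *every* quadratic term of that sub-problem at the current
iterate, adding proximal terms `(s_i/2)‖u − u^k‖²`. The minimizer is then
an explicit gradient step with fixed step `1/(s₁+s₂)` — no line search,
no FFT structure assumptions. Convergence requires each linearization
constant to dominate its quadratic's curvature:

    ucTV/TVcDM:  s₁ ≥ λ_max(AᵀA),      s₂ ≥ β·λ_max(DᵀD)
    DDcTV:       s₁ ≥ β₁·λ_max(DᵀD),   s₂ ≥ β₂·λ_max(AᵀA)

The split and multiplier updates are all closed forms: grouped 2D
shrinkage (threshold α/β for ucTV, 1/β₁ for DDcTV), an ℓ2-ball projection
of the data residual (DDcTV), and for TVcDM an ℓ1-ball projection of the
pixelwise gradient-magnitude image followed by rescaling each pixel's
2-vector to the projected magnitude. ε = 0 and t = 0 are legal degenerate
radii (the 0/0 quotient is defined as 0), turning the DDcTV constraint
into the equality `Au = g`.

**Inner iterations.** The plain scheme takes a single gradient step per
outer iteration and converges slowly. Since the linearized image update is
exactly a fixed-step gradient-descent step on the frozen sub-problem,
repeating only that step `n_inner` times per outer iteration (splits and
multipliers held fixed) accelerates convergence at no algorithmic risk;
`n_inner = 1` reproduces the plain scheme bit-for-bit. The data and TV
residual targets are constant within an inner loop, so the constants are
hoisted and each inner step costs two projector applications plus two
gradient stencils.

**Initialization and stopping.** All iterates start at zero (this makes
`g = 0` an exact fixed point and is the common ADMM default). The solvers
run a fixed outer budget; an optional early-stop tolerance (off by
default) halts on truth-RMSE or relative image change. A divergence guard
aborts with a descriptive error if iterates go non-finite or exceed 10⁶ ×
the data scale, rather than returning NaNs.

## Step-size policy

`λ_max(AᵀA)` and `λ_max(DᵀD)` are estimated by power iteration (seeded
uniform start vector, default 1000 sweeps, relative-change tolerance
1e-6). Because power iteration approaches the eigenvalue from below, the
bounds are multiplied by a safety factor, default 1.05. Values below 1 are
accepted deliberately: they violate the convergence condition and exist to
exercise the divergence guard. For first-difference gradients
`λ_max(DᵀD) ≤ 8` on every grid, approached from below as the grid grows.

## The projector

Pixel-driven parallel-beam Radon transform: for each view, each pixel
center is projected onto the detector axis (`t = x cosθ + y sinθ`) and its
value linearly interpolated into the two nearest bins with weights summing
to `pixel_size²/bin_length`; pixels projecting off the detector contribute
nothing. Backprojection reuses identical weights, so the pair is an exact
adjoint — mandatory here, because the solvers' convergence theory assumes
`Aᵀ` is the true adjoint, and the test suite checks the inner-product
identity at 1e-10. The operator is materialized once as a sparse CSR
matrix (two nonzeros per pixel per view), which keeps the many
matrix-vector products cheap; `as_matrix` exposes the same weights as an
explicit matrix for small problems and is compared entrywise against the
loop-based implementation in tests.

Conventions: angles `θ_k = kπ/n_a` on the half-open `[0, π)` (avoiding the
duplicated 0/π view), rotation center at pixel index `n/2`, detector bin
centers `−(n_p/2 − 1) … n_p/2` times the bin length. Units are pixels
(pixel size = bin length = 1) throughout the studies.

## Chambolle–Pock baseline

For the DDcTV model the package includes the standard first-order
primal–dual iteration with the stacked operator `K = (A; D)`: the data
dual is updated by a global ℓ2 shrink of `p + σ(Aū − g)` by σε (the prox
of the conjugate of the shifted-ball indicator), the TV dual by a
per-pixel clamp onto the unit disk, the primal by a `τ`-step with
over-relaxation `θ = 1`. Steps are `σ = λ/L`, `τ = 1/(λL)` with `λ = 1`
and `L = ‖K‖₂` estimated by power method; both `λ` and `L` are exposed as
overrides since conventions for the step split vary.

## Phantoms (the synthetic-data surface)

* `shepp_logan` — the standard ten-ellipse head phantom with modified
  contrasts (values in [0, 1]), evaluated at pixel centers on the
  normalized square.
* `forbild_like` — a simplified head phantom in the FORBILD spirit (skull
  shell, brain, ventricle-like ellipses, small high-contrast insert). It
  is a documented stand-in, not the licensed FORBILD parameter set, so
  tests needing exact values use Shepp-Logan.
* `disk` — uniform disk centered at the rotation center (its sinogram is
  rotation-invariant up to edge pixelization; total mass per view is
  exactly constant).
* `blocks` — a chest-like stand-in for a clinical slice: body ellipse,
  lungs, spine, mediastinum, thin vessels and small nodules, **plus smooth
  intensity modulations**. The smooth components matter: a piecewise-
  constant phantom is exactly TV-recoverable from very few views, which
  drives both solvers' RMSE to the float level at solver-dependent rates
  and makes solver comparisons and view-count trends meaningless. Real CT
  slices are not piecewise constant; the smooth terms reproduce the
  feature that makes sparse-view RMSE floors nonzero.

What the generator does **not** emulate: measurement noise (the studies
are noiseless by design), beam hardening/scatter, fan-beam or 3D
geometry, and detector blur. Passing tests therefore demonstrate solver
and model correctness on consistent synthetic data, not clinical image
quality.

## The validation studies and their problem sizes

All studies default to 64 × 64 images — large enough to show the
qualitative behaviour, small enough that the whole battery runs in
minutes on one CPU.

1. **inverse_crime** (Shepp-Logan, 64 bins × 64 views, DDcTV, ε = 0,
   β = 1, 50 inner steps): data generated with the package's own
   projector give an exactly consistent square system, so the solver must
   reproduce the phantom to numerical accuracy. Success is RMSE ≤ 1e-4 —
   well below 1/256 ≈ 3.9e-3, the RMSE at which an 8-bit display can no
   longer show a difference. At this scale the threshold is typically
   crossed within a few hundred outer iterations.
2. **beta_sweep** (forbild_like, 25 views, β ∈ {0.01, 0.1, 1, 10, 100},
   500 outer iterations): final RMSE ranks the convergence speeds. β = 10
   is the fastest here. A caution documented from our measurements: the
   penalty is dimensionful, so the *ordering of the extremes* depends on
   problem scale — at 64² the under-penalized β = 0.01 run is the
   slowest, while at larger image/data scales the over-penalized β = 100
   run is. Too large or too small is always slow; which extreme is worse
   is condition-dependent.
3. **inner_sweep** (same geometry, β = 10, n_inner ∈ {1, 50, 100, 150,
   200}, 300 outer iterations): the plain one-step scheme is far slower
   than any inner-iteration variant; returns diminish beyond ~50 steps
   while cost grows linearly.
4. **cp_compare** (blocks phantom, views ∈ {20, 40, 60, 80, 100}, ε = 0):
   FL-ADMM (β = 10, 50 inner steps, 400 outer) versus Chambolle–Pock
   (35000 iterations). Budgets are chosen so each solver reaches its RMSE
   plateau ("matched long iteration counts"); matching raw step counts
   instead would compare a converged solver against an unconverged one.
   Both RMSE columns decrease monotonically with view count, and at 50
   views the two plateaus agree to within ~15–20% — the two algorithms
   solve the same convex program, but with ε = 0 the solution set is not
   a singleton at sparse views and the algorithms' parameter choices
   land them at slightly different accuracy, the same pattern the
   published per-view tables for this comparison show (relative gaps
   growing from ~1% at 20 views to ~20% at 100).

## Numerical choices and edge cases

* Zero-magnitude pixels in the 2D shrinkage and in the TVcDM rescale map
  to zero (the unique minimizer; 0/0 := 0).
* The ℓ1-ball projection is the O(n log n) sort-and-threshold simplex
  projection restricted to nonnegative inputs — its only consumer projects
  gradient-magnitude images, which are nonnegative by construction. Ties
  in the sorted values need no handling because the water-filling level
  comes from cumulative sums.
* `Dᵀ` is the mechanical transpose of the backward-difference stencil,
  not an independently discretized divergence; this is what makes the
  adjoint identity exact.
* Float64 in memory everywhere; float32 on disk (TIFF/CSV), with
  convergence CSVs serialized at 17 significant digits so replays are
  byte-comparable.
* Study runs are deterministic given their spec; the only randomness is
  the seeded power-method start vector, whose effect on the step sizes is
  bounded by the power-iteration tolerance (1e-6 relative).

## Known limitations

Parallel-beam 2D only; no noise models; no acceleration variants
(over-relaxed, generalized, or Nesterov-style linearized ADMM); the
full-scale 256² inverse-crime run (thousands of outer iterations with 50
inner steps each) is hours of compute and is not part of the default
battery — the desk-scale study demonstrates the same exact-recovery
property in seconds.
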