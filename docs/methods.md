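# Methods

## Model

Two column-wise normalized data blocks X (n × p) and Y (n × q) — in the
imaging workflow, basis coefficients of the predictor and response image
stacks — and a univariate outcome Z are decomposed into K rank-one
components. Component scores are t = X w_X and u = Y w_Y; the weights
maximize

    L(w_X, w_Y) = μ_XY tᵀu + μ_XZ tᵀZ + μ_YZ uᵀZ − P_λX(w_X) − P_λY(w_Y)

subject to ‖w_X‖₂ = ‖w_Y‖₂ = 1, where the supervision proportions lie on
the unit simplex (μ_XY + μ_XZ + μ_YZ = 1) and P_λ is an ℓ1 penalty. The
stationary conditions give closed-form coordinate updates by
soft-thresholding:

    w̃_X = h_λX( Xᵀ(μ_XY u + μ_XZ Z) ),   ŵ_X = w̃_X / ‖w̃_X‖₂
    w̃_Y = h_λY( Yᵀ(μ_XY t + μ_YZ Z) ),   ŵ_Y = w̃_Y / ‖w̃_Y‖₂

alternated to convergence; h_λ(y) = sign(y)(|y| − λ)₊. After each
component, both blocks are deflated by the score-loading rank-one term
(p = Xᵀt/tᵀt, X ← X − t pᵀ; likewise for Y), which makes successive
scores orthogonal in the unpenalized case.

Limits worth knowing: with μ_XZ = μ_YZ = 0 and λ = 0 the fixed point is
the leading singular pair of XᵀY (two-block PLS); with μ_XY = 0 both
weight vectors are driven by Z alone and the cross-modality coupling is
lost — the *over-supervised* regime, in which region recovery collapses
on strong-signal synthetic data.

### Penalty bookkeeping

The objective's penalty is reported as P_λ(w) = 2λ‖w‖₁ in
`objective_value` (the package's stated contract), while the per-half-step
monotone trace recorded inside `fit_component` uses λ‖w‖₁, the form for
which the soft-threshold-then-normalize update is the exact maximizer of
the unit-ball subproblem (as in penalized matrix decomposition). The two
differ only by relabeling λ; the trace form is the one whose ascent
property the implementation asserts (nondecreasing within 1e-8 per
half-step).

## Algorithmic choices

- **Initialization.** Scores start at their *natural* scale:
  t₀ = X v₁(X), u₀ = Y v₁(Y) (the leading score σ₁u₁ of each block), not
  unit norm. The loop never renormalizes scores, so a unit-norm start
  would make the first soft-threshold see gradients smaller than every
  later iteration by a factor ≈ ‖score‖ — any penalty in the useful range
  would then annihilate the weights at iteration one. A seeded
  random-score init is available (`init="random"`) for robustness checks.
  The SVD start vector is fixed, so repeated fits are bitwise identical.
- **Convergence.** Relative ℓ2 change of the concatenated weight pair
  below `tol` (default 1e-6), `max_iter` 500; non-convergence sets a flag
  and warns, it is not an error. Annihilation of a driven weight vector
  raises `OverPenalizedError` naming the offending λ.
- **Undriven blocks.** If a block's update blend has no nonzero
  coefficient (e.g. the Y block at μ = (0, 1, 0)), that block is
  decoupled from the objective; it keeps the unpenalized leading singular
  direction rather than raising the annihilation error.
- **Sign convention.** When μ_XZ = μ_YZ = 0 the solution is invariant to
  jointly flipping (w_X, t, w_Y, u); the fit flips so the largest-|·|
  entry of w_X is positive, for reproducible tests. With supervision
  active the outcome terms pin the sign and no flip is applied (a flip
  would negate tᵀZ and uᵀZ and leave the optimum).
- **Outcome scaling.** Z is centered and scaled to unit *variance*,
  exactly like a data column. Scaled to unit ℓ2 norm instead, ‖Z‖ = 1
  against natural-scale scores ‖t‖ ≈ 30 leaves the supervision terms
  ~30× smaller than the cross-block term and the μ proportions
  effectively inert; unit variance puts tᵀZ on a single-column footing.
- **Penalty selection.** Per component and per block, candidates lie on a
  16-point logarithmic grid from λ_max (the sup-norm of the init
  gradient, the smallest penalty annihilating the whole vector on entry)
  down to λ_max·10⁻³. Each candidate fit is scored by
  BIC(λ) = log(RSS/(nm)) + df·log(nm)/(nm), with RSS the block's
  deflation residual sum of squares and df the nonzero-weight count;
  annihilating candidates are skipped. λ_X is optimized first with λ_Y
  anchored at the grid's geometric middle, then λ_Y at the selected λ_X.
  The BIC minimum typically sits near the sparse end of the path, so the
  grid density matters: 8 points over three decades (steps of ×2.4) skip
  the df range where the minimum lives; 16 points resolve it.

## Basis expansion

The radial cubic B-spline profile, with d = dist − h,

    φ(dist) = (h³ − 3h²d + 3hd² + 3d³)/(4h³)   d ≤ 0
              (h − d)³/(4h³)                    0 < d ≤ h
              0                                 d > h

is 1 at the knot, 1/4 at distance h, 0 beyond 2h, and C² at the joins.
The 1/(4h³) normalization is the standard one for this profile; any
constant rescaling is absorbed by the unit-norm weight constraint, so
results depend on it only through the λ scale. Knots form a regular
lattice at integer multiples of the spacing with one spacing of margin
beyond the bounding box, so every in-mask voxel lies within 2h of a
knot; h = spacing·√d (d = 2 or 3). Coordinates are 0-based voxel
indices and distances are in voxel units — knots in millimeter space
would require the NIfTI affine and are out of scope. Rows of the sparse
design matrix B are built only for in-mask voxels (via a KD-tree range
query at radius 2h); columns with empty in-mask support are dropped and
the surviving knot indices recorded.

Because recovered patterns live in the span of 2h-wide bumps, any
selected knot lights a ball of radius up to 2h in pixel space: the
achievable specificity of binarized maps is resolution-limited by the
knot spacing, which bounds the attainable c-index from above at small
image sizes.

## Synthetic data generator

The generator emulates a two-modality latent factor design with known
truth regions:

    t ~ iid N(0, I_K) rows;   u = t·diag(w_u) + ε,  ε ~ N(0, I_K)
    X = t W_X⁻;               Y = u W_Y⁻ + e₀ E₀;       Z = u w_z

with W_X = s_X·w_x_scalar, W_Y = s_Y·w_y_scalar built from binary truth
masks and ⁻ the Moore–Penrose generalized inverse. Defaults are the
benchmark conditions: n = 50, K = 2, 100 × 100 images, w_u = (1, w_u0)
with w_u0 = 0.8, w_x_scalar = 5, w_y_scalar = 1, e₀ = 0.005,
w_z = (1, 0). Noteworthy consequences, all asserted by tests:

- **X is noiseless** (noise enters Y only) and exactly zero outside the
  true X regions, since pinv of a disjoint-column weight matrix is
  supported where the weights are.
- With e₀ = 0 and w_y_scalar = 1, Y·W_Y = u exactly (pinv identity), so
  latent response scores are recoverable to machine precision.
- Z equals the w_z-flagged column of u exactly; w_u is interpreted
  componentwise (u_k = (w_u)_k t_k + ε_k), the only dimensionally
  consistent reading.
- The pixel scale of the signal is 1/(area·w_y_scalar) per unit score,
  so w_y_scalar = 20 buries the response signal well below the e₀ noise
  floor (the weak-signal regime), while w_y_scalar = 1 sits above it.

Truth regions default to disjoint filled discs (radius 10% of the image
side) at the four quadrant centers, X and Y regions at different
locations. Real shapes of interest can be substituted via the
`true_image_spec` hook. The generator does *not* emulate registration
error, anatomical covariance, spatial autocorrelation of noise, or
scanner effects; passing benchmarks here demonstrates algorithmic
correctness and the supervision mechanics, not performance on real
images.

## Benchmark harness

`run_grid` runs, for each supervision pair (μ_XZ, μ_YZ) on the
{0, 0.25, 0.5, 0.75} grid with μ_XZ + μ_YZ ≤ 1 (13 pairs) and each
repetition: generate → basis-expand (2-pixel knots) → fit K components
with BIC-selected penalties → binarize composite maps at tolerance
1e-10 (separating structural zeros from float residue) → score with the
c-index. The same per-rep seeds (spawned from one base seed via
`SeedSequence`) are reused across pairs, so comparisons across
supervision settings are paired. Estimated components are matched to
truth components by greedy assignment on the *signed* c-index averaged
over the two blocks — one permutation per fit, shared by both blocks,
since a component is common to them; signed, because only positive
agreement indicates recovery (on dense selections an anti-match can
exceed the true match in magnitude).

Problem sizes in the shipped tests are chosen to keep the full suite
within a few minutes on one core: the grid-ordering checks run 40 × 40
images with 20 repetitions, and the recovery check runs the default
100 × 100 conditions over 10 generator seeds. At 40 × 40 the disc radius
scales to 4 px against a 2h ≈ 5.7 px bump radius, so absolute c-index
values sit well below those attainable at 100 × 100; the benchmark's
claims there are orderings across supervision settings, not absolute
levels.

## Known limitations

- With K > 1 latent components, the *identity* of a fitted component can
  switch between latent factors as μ or λ vary; per-component quantities
  such as corr(t₁, Z) are therefore not monotone in the supervision
  proportions on multi-component data, although they are on
  single-component data (where the premise of the comparison holds).
  Downstream comparisons should match components first.
- Binarized-map specificity is bounded by the 2h bump support; finer
  knot spacing trades this against q and runtime.
- Anisotropic voxels, physical-space knots, >2 modalities, and non-ℓ1
  penalty structures are out of scope.
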