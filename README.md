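# ssma — supervised sparse multivariate analysis of paired image modalities

`ssma` estimates sparse, outcome-supervised associations between two
voxelwise imaging modalities — e.g. an amyloid-PET image stack as the
predictor and gray-matter structural MRI as the response — using a
two-step dimension reduction:

1. **Radial B-spline basis expansion.** Each vectorized image stack
   `S` (n subjects × N voxels) is projected onto q ≪ N smooth radial
   cubic B-spline bumps φₖ centered on a regular knot lattice:
   `X = S_X B`, `Y = S_Y B`, where `B[j,k] = φₖ(‖v_j − κ_k‖)` and each
   bump has compact support of radius 2h (h = spacing·√d is the knot
   distance).

2. **Supervised sparse decomposition (SSMA).** With scores `t = X w_X`
   and `u = Y w_Y` and a univariate clinical outcome `Z`, each component
   maximizes

   ```
   L(w_X, w_Y) = μ_XY tᵀu + μ_XZ tᵀZ + μ_YZ uᵀZ − P_λX(w_X) − P_λY(w_Y)
   ```

   subject to `‖w_X‖₂ = ‖w_Y‖₂ = 1`, with `μ_XY + μ_XZ + μ_YZ = 1` and
   an ℓ1 penalty solved in closed form by soft-thresholding,
   `h_λ(y) = sign(y)(|y| − λ)₊`. With `μ_XZ = μ_YZ = 0` and λ = 0 this
   is two-block PLS (the leading singular pair of `XᵀY`); supervision
   tilts the weights toward outcome-relevant directions. Further
   components come from rank-one deflation, and penalties are selected
   per component by a BIC search along the regularization path.

A fitted weight vector maps back to voxel space through the basis as a
*composite* function `ψ(v) = Σₖ φₖ(v) wₖ` — a flexible spatial pattern
built from spherical bumps — so each component yields a paired pattern
(ψ_X, ψ_Y) of associated regions across modalities, plus subject scores
usable in ordinary downstream statistics.

The package also ships the simulation benchmark used to characterize the
method: a latent factor generator with known truth regions, and a
c-index (Youden) evaluation harness measuring how well the sparse
patterns recover those regions as supervision varies — including the
collapse under *over-supervision* (μ_XY = 0), where the cross-modality
term vanishes.

Audience: methodologists and imaging statisticians who want a
reproducible reference implementation of basis-expanded supervised
sparse PLS/CCA for paired image stacks, with no clinical data required.

## Worked example

Simulate a paired dataset with known truth regions, basis-expand it,
fit a supervised two-component model, and score region recovery:

```python
import numpy as np
from ssma import (SimConfig, generate_dataset, make_knot_grid,
                  build_basis_matrix, project_images, SSMA,
                  SupervisionWeights, binarize_weights, c_index,
                  match_components)

cfg = SimConfig(image_shape=(40, 40), seed=0)   # n=50, K=2, discs truth
data = generate_dataset(cfg)
stack_x, stack_y = data.stacks()

grid = make_knot_grid(cfg.image_shape, spacing=2)
basis = build_basis_matrix(stack_x, grid)
X = project_images(stack_x, basis)              # 50 x 484
Y = project_images(stack_y, basis)

model = SSMA(X, Y, data.Z, n_components=2,
             supervision=SupervisionWeights.from_outcome_weights(0.25, 0.25))
res = model.fit()
print(res.summary())

sel_x = [binarize_weights(basis, c.w_x) for c in res.components]
sel_y = [binarize_weights(basis, c.w_y) for c in res.components]
perm = match_components(sel_x, sel_y, data.s_x_true, data.s_y_true)
for k in range(2):
    cx = c_index(sel_x[perm[k]], data.s_x_true[:, k]).c_index
    cy = c_index(sel_y[perm[k]], data.s_y_true[:, k]).c_index
    print(f"component {k+1}: c-index X = {cx:.3f}, Y = {cy:.3f}")
```

Output:

```
Supervised sparse multivariate analysis
  n = 50, p = 484, q = 484, K = 2
  supervision: mu_XY = 0.500, mu_XZ = 0.250, mu_YZ = 0.250

comp   lambda_x   lambda_y  nnz_x  nnz_y  corr(t,u)  corr(t,Z)  corr(u,Z)  iters  conv
   1    0.09394      88.42    137     37      0.717     -0.040     -0.048      6  True
   2      23.03      81.06     69     39      0.712     -0.709     -0.997      2  True
component 1: c-index X = 0.693, Y = 0.770
component 2: c-index X = 0.373, Y = 0.769
```

The summary shows, per component, the BIC-selected penalties, the number
of retained basis weights, and the score correlations — here the second
fitted component is the outcome-aligned one (|corr(u, Z)| ≈ 1), which is
why recovered components are matched to truth components before scoring.
The c-index (sensitivity − (1 − specificity)) is 1 for perfect region
recovery and 0 in expectation for any uninformative selector; values
near 0.7 mean the truth discs are found with a modest halo, whose width
is bounded by the 2h support radius of the basis bumps.

The same workflows are scriptable from the shell via the `ssma` CLI
(`simulate`, `fit`, `benchmark`, `score` subcommands); real data enter
as one NIfTI volume per subject plus a CSV outcome, and fitted patterns
are written back as NIfTI composite maps. `run_grid` reproduces the full
supervision-grid benchmark (13 (μ_XZ, μ_YZ) pairs × repetitions) as a
c-index table plus pixelwise selection-probability maps.

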