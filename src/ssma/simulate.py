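"""Synthetic paired-image data generator and simulation benchmark grid.

The generator produces paired image stacks (X, Y) and an outcome Z from a
latent two-block factor model:

    t ~ iid N(0, I_K) rows                     (predictor scores)
    u = t diag(w_u) + eps,  eps ~ N(0, I_K)    (response scores)
    X = t W_X^-                                (noiseless predictor images)
    Y = u W_Y^- + e0 E0                        (response images + pixel noise)
    Z = u w_z                                  (outcome from response scores)

where W_X = s_X * w_x_scalar and W_Y = s_Y * w_y_scalar are N x K weight
images built from binary ground-truth region masks s_X, s_Y (disjoint
filled discs by default), M^- denotes the Moore-Penrose generalized
inverse, and E0 has iid standard-normal entries.  w_u = (1, w_u0, ...)
controls how strongly the second component couples the two modalities;
w_y_scalar controls how strongly the response scores express in the pixels
(large w_y_scalar = weak expression, since the generalized inverse scales
as 1/w_y_scalar).  Noise enters Y only; X is exactly zero outside the true
X regions.

Defaults are the benchmark conditions: n = 50 subjects, K = 2 components,
100 x 100 images, w_u0 = 0.8, w_x_scalar = 5, w_y_scalar = 1, e0 = 0.005,
w_z = (1, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .basis import ImageStack, make_knot_grid, build_basis_matrix, project_images
from .model import SSMA, SupervisionWeights
from .evaluate import binarize_weights, c_index, match_components, selection_probability_map

__all__ = ["SimConfig", "SimData", "make_true_images", "generate_dataset",
           "run_grid", "GridResult", "MU_GRID"]

#: the 13 supervision pairs (mu_XZ, mu_YZ) with mu_XZ + mu_YZ <= 1 on the
#: {0, 0.25, 0.5, 0.75} grid
MU_GRID = [
    (x, y)
    for x in (0.0, 0.25, 0.5, 0.75)
    for y in (0.0, 0.25, 0.5, 0.75)
    if x + y <= 1.0
]


@dataclass
class SimConfig:
    n: int = 50
    n_components: int = 2
    image_shape: tuple = (100, 100)
    w_u0: float = 0.8
    w_x_scalar: float = 5.0
    w_y_scalar: float = 1.0
    e0: float = 0.005
    w_z: tuple = (1.0, 0.0)
    seed: int = 0
    true_image_spec: str = "discs"     # "discs" or "full"
    disc_radius_frac: float = 0.1      # disc radius as a fraction of image side

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.e0 < 0:
            raise ValueError("e0 must be nonnegative")
        self.image_shape = tuple(int(s) for s in self.image_shape)
        self.w_z = tuple(float(v) for v in self.w_z)
        if len(self.w_z) != self.n_components:
            raise ValueError("w_z must have one entry per component")


@dataclass
class SimData:
    """One synthetic dataset with its generating truth."""

    X: np.ndarray            # n x N predictor images
    Y: np.ndarray            # n x N response images
    Z: np.ndarray            # n outcome
    t_true: np.ndarray       # n x K latent predictor scores
    u_true: np.ndarray       # n x K latent response scores
    s_x_true: np.ndarray     # N x K binary truth masks, predictor block
    s_y_true: np.ndarray     # N x K binary truth masks, response block
    config: SimConfig

    def stacks(self):
        """The X and Y image stacks as :class:`ImageStack` objects."""
        shape = self.config.image_shape
        return ImageStack(self.X, shape), ImageStack(self.Y, shape)


def _disc_mask(shape, center, radius):
    grids = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return (d2 <= radius**2).ravel()


def make_true_images(image_shape, n_components: int, spec: str = "discs",
                     seed: int = 0, disc_radius_frac: float = 0.1):
    """Binary ground-truth region masks for each component and block.

    The default "discs" layout places one filled disc per (block, component)
    at distinct quadrant centers — X and Y regions at different locations,
    disjoint across components — with radius ``disc_radius_frac`` of the
    image side.  Returns (s_x_true, s_y_true), each N x K with columns in
    C-order vectorization.  Deterministic given the arguments.
    """
    image_shape = tuple(int(s) for s in image_shape)
    N = int(np.prod(image_shape))
    if spec == "full":
        ones = np.ones((N, n_components), dtype=bool)
        return ones, ones.copy()
    if spec != "discs":
        raise ValueError(f"unknown true-image spec {spec!r}")
    side = min(image_shape)
    radius = disc_radius_frac * side
    # quadrant centers, visited in a fixed order; X and Y take different ones
    fracs = [(0.25, 0.25), (0.75, 0.75), (0.75, 0.25), (0.25, 0.75)]
    if 2 * n_components > len(fracs):
        raise ValueError("disc layout supports at most 2 components")
    centers = [tuple(f * (s - 1) for f, s in zip(fr, image_shape)) for fr in fracs]
    for c in centers[: 2 * n_components]:
        if any(ci - radius < -0.5 or ci + radius > s - 0.5
               for ci, s in zip(c, image_shape)):
            raise ValueError("true regions overflow the image")
    s_x = np.zeros((N, n_components), dtype=bool)
    s_y = np.zeros((N, n_components), dtype=bool)
    for k in range(n_components):
        s_x[:, k] = _disc_mask(image_shape, centers[k], radius)
        s_y[:, k] = _disc_mask(image_shape, centers[n_components + k], radius)
    return s_x, s_y


def generate_dataset(config: SimConfig) -> SimData:
    """Draw one dataset from the latent factor model (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    K = config.n_components
    s_x, s_y = make_true_images(
        config.image_shape, K, config.true_image_spec,
        config.seed, config.disc_radius_frac,
    )
    W_X = s_x.astype(float) * config.w_x_scalar
    W_Y = s_y.astype(float) * config.w_y_scalar
    if np.linalg.matrix_rank(W_X) < K or np.linalg.matrix_rank(W_Y) < K:
        raise ValueError("true weight images are rank deficient")
    w_u = np.ones(K)
    if K >= 2:
        w_u[1:] = config.w_u0
    t = rng.standard_normal((config.n, K))
    eps = rng.standard_normal((config.n, K))
    u = t * w_u + eps
    X = t @ np.linalg.pinv(W_X)
    Y = u @ np.linalg.pinv(W_Y)
    if config.e0 > 0:
        Y = Y + config.e0 * rng.standard_normal(Y.shape)
    Z = u @ np.asarray(config.w_z)
    return SimData(X=X, Y=Y, Z=Z, t_true=t, u_true=u,
                   s_x_true=s_x, s_y_true=s_y, config=config)


@dataclass
class GridResult:
    """Benchmark output: mean c-index table plus selection-probability maps."""

    table: pd.DataFrame
    #: {(mu_xz, mu_yz): {"X"/"Y": list over components of ProbabilityMap}}
    probability_maps: dict
    per_rep: pd.DataFrame
    config: SimConfig
    knot_spacing: float
    reps: int


def run_grid(config: SimConfig, mu_pairs=None, reps: int = 100,
             knot_spacing: float = 2.0, lambda_grid_size: int = 16,
             binarize_tol: float = 1e-10, progress=None) -> GridResult:
    """Run the simulation benchmark over a grid of supervision pairs.

    For each (mu_XZ, mu_YZ) pair and each repetition: generate a dataset,
    basis-expand both image stacks with ``knot_spacing``-pixel knots, fit a
    K-component SSMA with BIC-selected penalties, binarize the composite
    weight maps and score them against the true regions with the c-index
    (components matched to truths).  The same per-rep seeds are reused
    across pairs, so comparisons across supervision settings are paired.

    Returns a :class:`GridResult` whose ``table`` has one row per pair with
    per-component and mean c-index columns for each block, and whose
    probability maps give the pixel-wise selection frequency over reps.
    """
    if mu_pairs is None:
        mu_pairs = MU_GRID
    for mx, my in mu_pairs:
        if mx + my > 1.0 + 1e-12 or mx < 0 or my < 0:
            raise ValueError(f"invalid supervision pair ({mx}, {my})")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    K = config.n_components

    # the basis and the truth masks are fixed across reps and pairs
    grid = make_knot_grid(config.image_shape, knot_spacing)
    probe = ImageStack(np.zeros((2, int(np.prod(config.image_shape)))),
                       config.image_shape)
    basis = build_basis_matrix(probe, grid)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in np.random.SeedSequence(config.seed).spawn(reps)]

    rows = []
    prob_maps = {}
    for mx, my in mu_pairs:
        sup = SupervisionWeights.from_outcome_weights(mx, my)
        sel_masks = {"X": [[] for _ in range(K)], "Y": [[] for _ in range(K)]}
        for r in range(reps):
            cfg_r = SimConfig(**{**asdict(config), "seed": rep_seeds[r]})
            data = generate_dataset(cfg_r)
            sx, sy = data.stacks()
            Xc = project_images(sx, basis)
            Yc = project_images(sy, basis)
            res = SSMA(
                Xc, Yc, data.Z, n_components=K, supervision=sup,
                lambda_x="auto", lambda_y="auto",
                lambda_grid_size=lambda_grid_size,
            ).fit()
            sel_x = [binarize_weights(basis, c.w_x, binarize_tol)
                     for c in res.components]
            sel_y = [binarize_weights(basis, c.w_y, binarize_tol)
                     for c in res.components]
            perm = match_components(sel_x, sel_y, data.s_x_true, data.s_y_true)
            row = {"mu_xz": mx, "mu_yz": my, "rep": r}
            for k in range(K):
                cx = c_index(sel_x[perm[k]], data.s_x_true[:, k]).c_index
                cy = c_index(sel_y[perm[k]], data.s_y_true[:, k]).c_index
                row[f"x_comp{k + 1}"] = cx
                row[f"y_comp{k + 1}"] = cy
                sel_masks["X"][k].append(sel_x[perm[k]])
                sel_masks["Y"][k].append(sel_y[perm[k]])
            rows.append(row)
            if progress is not None:
                progress(mx, my, r)
        prob_maps[(mx, my)] = {
            blk: [selection_probability_map(sel_masks[blk][k]) for k in range(K)]
            for blk in ("X", "Y")
        }

    per_rep = pd.DataFrame(rows)
    xcols = [f"x_comp{k + 1}" for k in range(K)]
    ycols = [f"y_comp{k + 1}" for k in range(K)]
    table = per_rep.groupby(["mu_xz", "mu_yz"], as_index=False)[xcols + ycols].mean()
    table["x_mean"] = table[xcols].mean(axis=1)
    table["y_mean"] = table[ycols].mean(axis=1)
    table["xy_mean"] = (table["x_mean"] + table["y_mean"]) / 2
    table = table[["mu_xz", "mu_yz"] + xcols + ["x_mean"] + ycols
                  + ["y_mean", "xy_mean"]]
    return GridResult(table=table, probability_maps=prob_maps, per_rep=per_rep,
                      config=config, knot_spacing=knot_spacing, reps=reps)
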