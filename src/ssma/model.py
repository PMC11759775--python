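"""Supervised sparse multivariate analysis (SSMA).

A PLS/CCA-like rank-one decomposition of two column-normalized data blocks
X (n x p) and Y (n x q) whose weight updates blend the cross-block
covariance with the covariance against a univariate outcome Z.  Each
component maximizes

    L(w_X, w_Y) = mu_XY t'u + mu_XZ t'Z + mu_YZ u'Z - P_lx(w_X) - P_ly(w_Y)

subject to unit-norm weights, where t = X w_X, u = Y w_Y, the supervision
proportions satisfy mu_XY + mu_XZ + mu_YZ = 1, and P_l is an l1 penalty
solved in closed form by soft-thresholding.  With mu_XZ = mu_YZ = 0 and no
penalty this is ordinary two-block PLS (the leading singular pair of X'Y);
supervision tilts the weights toward outcome-relevant directions.
Components beyond the first are obtained by rank-one deflation of both
blocks by their score-loading product.

The model-fitting surface follows the statsmodels convention: build an
:class:`SSMA` model from data, call :meth:`SSMA.fit`, and work with the
returned :class:`SSMAResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.sparse.linalg import svds

__all__ = [
    "SupervisionWeights",
    "SSMAConfig",
    "ComponentFit",
    "SSMA",
    "SSMAResults",
    "OverPenalizedError",
    "normalize_columns",
    "soft_threshold",
    "objective_value",
    "fit_component",
    "deflate",
    "select_lambda",
]


class OverPenalizedError(ValueError):
    """Raised when soft-thresholding annihilates an entire weight vector."""


@dataclass(frozen=True)
class SupervisionWeights:
    """Supervision proportions (mu_XY, mu_XZ, mu_YZ) on the unit simplex."""

    mu_xy: float
    mu_xz: float = 0.0
    mu_yz: float = 0.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        total = self.mu_xy + self.mu_xz + self.mu_yz
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"supervision proportions sum to {total}, expected 1")

    @classmethod
    def from_outcome_weights(cls, mu_xz: float, mu_yz: float) -> "SupervisionWeights":
        """Build from the two outcome proportions; mu_XY takes the remainder."""
        return cls(mu_xy=1.0 - mu_xz - mu_yz, mu_xz=mu_xz, mu_yz=mu_yz)


@dataclass
class SSMAConfig:
    n_components: int = 1
    supervision: SupervisionWeights = field(
        default_factory=lambda: SupervisionWeights(1.0, 0.0, 0.0)
    )
    lambda_x: object = "auto"          # nonnegative float or "auto"
    lambda_y: object = "auto"
    lambda_grid_size: int = 16
    tol: float = 1e-6
    max_iter: int = 500
    scale_columns: bool = True
    init: str = "svd"                  # "svd" or "random"
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ComponentFit:
    """One rank-one component: sparse unit-norm weights, scores and loadings."""

    w_x: np.ndarray
    w_y: np.ndarray
    t: np.ndarray
    u: np.ndarray
    p_loading: np.ndarray = None
    q_loading: np.ndarray = None
    lambda_x: float = 0.0
    lambda_y: float = 0.0
    n_iter: int = 0
    converged: bool = True
    objective_trace: np.ndarray = None


def normalize_columns(M, center: bool = True, scale: bool = True):
    """Center and/or scale columns; returns (normalized, means, scales).

    Standard deviations use the n-1 denominator.  Constant columns are
    centered but left unscaled (scale recorded as 1) with a warning.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("expected a nonempty 2-D matrix")
    if M.shape[0] < 2:
        raise ValueError("need at least 2 rows to normalize columns")
    means = M.mean(axis=0) if center else np.zeros(M.shape[1])
    out = M - means
    if scale:
        scales = out.std(axis=0, ddof=1)
        constant = scales <= 1e-12
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant column(s) left unscaled",
                stacklevel=2,
            )
            scales = np.where(constant, 1.0, scales)
        out = out / scales
    else:
        scales = np.ones(M.shape[1])
    return out, means, scales


def soft_threshold(y, lam: float):
    """Elementwise sign(y) * max(|y| - lam, 0)."""
    if lam < 0:
        raise ValueError(f"lam must be nonnegative, got {lam}")
    y = np.asarray(y, dtype=float)
    return np.sign(y) * np.maximum(np.abs(y) - lam, 0.0)


def objective_value(t, u, Z, w_x, w_y, sup: SupervisionWeights,
                    lam_x: float, lam_y: float) -> float:
    """The supervised objective mu_XY t'u + mu_XZ t'Z + mu_YZ u'Z - 2 lx|w_x|1 - 2 ly|w_y|1."""
    t, u, Z = (np.asarray(v, float).ravel() for v in (t, u, Z))
    if not (t.size == u.size == Z.size):
        raise ValueError("t, u, Z must have the same length")
    return float(
        sup.mu_xy * (t @ u)
        + sup.mu_xz * (t @ Z)
        + sup.mu_yz * (u @ Z)
        - 2 * lam_x * np.abs(w_x).sum()
        - 2 * lam_y * np.abs(w_y).sum()
    )


def _leading_score(M, rng=None):
    """Leading score sigma_1 * u_1 = M v_1: the score a unit-norm weight along
    the leading right singular direction would produce.

    Used to initialize the iteration at the scores' natural scale, so the
    very first soft-threshold sees gradients on the same scale as every
    later iteration (a unit-norm score init would make the first gradient
    ~||score|| times smaller than the rest of the trajectory and let any
    meaningful penalty annihilate the weights on iteration one).
    """
    M = np.asarray(M, float)
    if min(M.shape) >= 3:
        v0 = np.ones(min(M.shape)) if rng is None else rng.standard_normal(min(M.shape))
        u, s, vt = svds(M, k=1, v0=v0)
        return s[0] * u[:, 0]
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    return s[0] * u[:, 0]


def _apply_sign_convention(comp: ComponentFit) -> ComponentFit:
    # flip both blocks jointly so the largest-|.| entry of w_x is positive;
    # joint flip keeps t'u (and the fitted optimum) invariant — only valid
    # without supervision terms, which pin the sign themselves
    if comp.w_x.size and np.abs(comp.w_x).max() > 0:
        pivot = comp.w_x[np.argmax(np.abs(comp.w_x))]
        if pivot < 0:
            comp.w_x = -comp.w_x
            comp.t = -comp.t
            comp.w_y = -comp.w_y
            comp.u = -comp.u
    return comp


def fit_component(X, Y, Z, sup: SupervisionWeights,
                  lambda_x: float = 0.0, lambda_y: float = 0.0,
                  tol: float = 1e-6, max_iter: int = 500,
                  init: str = "svd", rng=None,
                  sign_convention: bool = True) -> ComponentFit:
    """Fit one SSMA component by alternating soft-thresholded updates.

    X and Y must already be column-normalized and Z centered with unit l2
    norm.  Alternates

        w_x <- h_lx( X'(mu_XY u + mu_XZ Z) ),  normalize;  t = X w_x
        w_y <- h_ly( Y'(mu_XY t + mu_YZ Z) ),  normalize;  u = Y w_y

    until the relative l2 change of the concatenated weights drops below
    ``tol``.  Raises :class:`OverPenalizedError` if a threshold wipes out a
    whole weight vector; non-convergence only sets ``converged=False``.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Z = np.asarray(Z, float).ravel()
    n = X.shape[0]
    if Y.shape[0] != n or Z.size != n:
        raise ValueError("X, Y, Z must share the row count")
    if lambda_x < 0 or lambda_y < 0:
        raise ValueError("penalties must be nonnegative")

    if init == "random":
        rng = np.random.default_rng(rng)
        t = rng.standard_normal(n)
        u = rng.standard_normal(n)
    else:
        t = _leading_score(X)
        u = _leading_score(Y)

    # a block whose update blend has no nonzero coefficient is decoupled from
    # the objective; it keeps the unpenalized single-block solution (leading
    # singular direction) instead of tripping the annihilation error
    drive_x = sup.mu_xy > 0 or sup.mu_xz > 0
    drive_y = sup.mu_xy > 0 or sup.mu_yz > 0
    w_x = np.zeros(X.shape[1])
    w_y = np.zeros(Y.shape[1])
    if not drive_x:
        w_x = X.T @ t
        w_x /= np.linalg.norm(w_x)
        t = X @ w_x
    if not drive_y:
        w_y = Y.T @ u
        w_y /= np.linalg.norm(w_y)
        u = Y @ w_y
    trace = []
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        w_x_old, w_y_old = w_x, w_y

        if drive_x:
            g_x = X.T @ (sup.mu_xy * u + sup.mu_xz * Z)
            w_x = soft_threshold(g_x, lambda_x)
            nx = np.linalg.norm(w_x)
            if nx == 0:
                raise OverPenalizedError(
                    f"lambda_x = {lambda_x} annihilates the X weight vector"
                )
            w_x = w_x / nx
            t = X @ w_x
        trace.append(_half_objective(t, u, Z, w_x, w_y, sup, lambda_x, lambda_y))

        if drive_y:
            g_y = Y.T @ (sup.mu_xy * t + sup.mu_yz * Z)
            w_y = soft_threshold(g_y, lambda_y)
            ny = np.linalg.norm(w_y)
            if ny == 0:
                raise OverPenalizedError(
                    f"lambda_y = {lambda_y} annihilates the Y weight vector"
                )
            w_y = w_y / ny
            u = Y @ w_y
        trace.append(_half_objective(t, u, Z, w_x, w_y, sup, lambda_x, lambda_y))

        delta = np.linalg.norm(np.concatenate([w_x - w_x_old, w_y - w_y_old]))
        if delta < tol * max(1.0, np.linalg.norm(np.concatenate([w_x, w_y]))):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SSMA component did not converge in {max_iter} iterations",
            stacklevel=2,
        )
    comp = ComponentFit(
        w_x=w_x, w_y=w_y, t=t, u=u,
        lambda_x=float(lambda_x), lambda_y=float(lambda_y),
        n_iter=n_iter, converged=converged,
        objective_trace=np.asarray(trace),
    )
    # the sign indeterminacy exists only when the outcome terms are absent;
    # with supervision the optimum's sign is pinned and must not be flipped
    if sign_convention and sup.mu_xz == 0 and sup.mu_yz == 0:
        comp = _apply_sign_convention(comp)
    return comp


def _half_objective(t, u, Z, w_x, w_y, sup, lam_x, lam_y):
    # trace recorded with the penalty form whose exact maximizer is the
    # soft-threshold update (lam * ||w||_1 per block), so each half-step is
    # a coordinate ascent step on this value
    return float(
        sup.mu_xy * (t @ u) + sup.mu_xz * (t @ Z) + sup.mu_yz * (u @ Z)
        - lam_x * np.abs(w_x).sum() - lam_y * np.abs(w_y).sum()
    )


def deflate(M, score):
    """Remove a score's rank-one contribution: returns (residual, loading).

    loading = M'score / score'score, residual = M - score loading'; the
    residual is orthogonal to the score in exact arithmetic.
    """
    M = np.asarray(M, float)
    score = np.asarray(score, float).ravel()
    ss = score @ score
    if ss == 0:
        raise ValueError("cannot deflate by an all-zero score")
    loading = M.T @ score / ss
    return M - np.outer(score, loading), loading


def select_lambda(X, Y, Z, sup: SupervisionWeights,
                  grid_size: int = 16, tol: float = 1e-6,
                  max_iter: int = 500) -> tuple:
    """BIC-guided coordinate search for the (lambda_x, lambda_y) pair.

    For each block, candidate penalties lie on a logarithmic grid from
    lambda_max (the smallest penalty annihilating the whole weight vector,
    read off the initial gradient's sup-norm) down to lambda_max * 1e-3.
    Each candidate component fit is scored by

        BIC(lambda) = log(RSS / (n m)) + df log(n m) / (n m)

    with RSS the block's deflation residual sum of squares and df the
    nonzero-weight count; candidates that annihilate a block are skipped.
    lambda_x is optimized first at the smallest lambda_y, then lambda_y at
    the selected lambda_x.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Z = np.asarray(Z, float).ravel()
    # natural-scale leading-score inits, so the init gradient's sup-norm is
    # the smallest penalty wiping out the whole weight vector on entry
    u0 = _leading_score(Y)
    t0 = _leading_score(X)
    lam_x_max = np.abs(X.T @ (sup.mu_xy * u0 + sup.mu_xz * Z)).max()
    lam_y_max = np.abs(Y.T @ (sup.mu_xy * t0 + sup.mu_yz * Z)).max()
    if lam_x_max <= 0 or lam_y_max <= 0:
        raise ValueError("degenerate penalty grid: zero initial gradient")
    grid_x = np.geomspace(lam_x_max, lam_x_max * 1e-3, grid_size)
    grid_y = np.geomspace(lam_y_max, lam_y_max * 1e-3, grid_size)

    def bic(M, score, w):
        resid, _ = deflate(M, score)
        nm = M.size
        rss = float((resid**2).sum())
        df = int(np.count_nonzero(w))
        return np.log(max(rss, 1e-300) / nm) + df * np.log(nm) / nm

    def try_fit(lx, ly):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # throwaway grid-search fits
                return fit_component(X, Y, Z, sup, lx, ly,
                                     tol=tol, max_iter=max_iter)
        except OverPenalizedError:
            return None

    best_lx, best_bic = None, np.inf
    ly_anchor = grid_y[len(grid_y) // 2]   # mid-grid anchor for the first pass
    for lx in grid_x:
        comp = try_fit(lx, ly_anchor)
        if comp is None:
            continue
        b = bic(X, comp.t, comp.w_x)
        if b < best_bic:
            best_lx, best_bic = lx, b
    if best_lx is None:
        raise OverPenalizedError("every lambda_x candidate annihilated the weights")

    best_ly, best_bic = None, np.inf
    for ly in grid_y:
        comp = try_fit(best_lx, ly)
        if comp is None:
            continue
        b = bic(Y, comp.u, comp.w_y)
        if b < best_bic:
            best_ly, best_bic = ly, b
    if best_ly is None:
        raise OverPenalizedError("every lambda_y candidate annihilated the weights")
    return float(best_lx), float(best_ly)


class SSMA:
    """Supervised sparse multivariate analysis model for paired data blocks.

    Parameters
    ----------
    X : (n, p) array
        Predictor block (e.g. basis coefficients of the predictor images).
    Y : (n, q) array
        Response block.
    Z : (n,) array
        Univariate outcome supervising the decomposition; centered and
        scaled to unit l2 norm internally.
    n_components : int
        Number of rank-one components K (deflation between components).
    supervision : SupervisionWeights or tuple
        (mu_XY, mu_XZ, mu_YZ) on the unit simplex.
    lambda_x, lambda_y : float or "auto"
        l1 penalties; "auto" runs the BIC coordinate search per component.

    Examples
    --------
    >>> model = SSMA(X, Y, Z, n_components=2,
    ...              supervision=SupervisionWeights(0.5, 0.25, 0.25))
    >>> res = model.fit()
    >>> res.scores_t.shape
    (n, 2)
    """

    def __init__(self, X, Y, Z, n_components: int = 1,
                 supervision=SupervisionWeights(1.0, 0.0, 0.0),
                 lambda_x="auto", lambda_y="auto", lambda_grid_size: int = 16,
                 tol: float = 1e-6, max_iter: int = 500,
                 scale_columns: bool = True, init: str = "svd", seed: int = 0):
        if not isinstance(supervision, SupervisionWeights):
            supervision = SupervisionWeights(*supervision)
        self.config = SSMAConfig(
            n_components=n_components, supervision=supervision,
            lambda_x=lambda_x, lambda_y=lambda_y,
            lambda_grid_size=lambda_grid_size, tol=tol, max_iter=max_iter,
            scale_columns=scale_columns, init=init, seed=seed,
        )
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        Z = np.asarray(Z, float).ravel()
        n = X.shape[0]
        if Y.shape[0] != n or Z.size != n:
            raise ValueError("X, Y, Z must share the subject dimension")
        if n_components > min(n - 1, X.shape[1], Y.shape[1]):
            raise ValueError(
                f"n_components = {n_components} exceeds min(n-1, p, q) = "
                f"{min(n - 1, X.shape[1], Y.shape[1])}"
            )
        self.X_raw, self.Y_raw, self.Z_raw = X, Y, Z
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns are expected
            self.X, self.x_means, self.x_scales = normalize_columns(
                X, center=True, scale=scale_columns
            )
            self.Y, self.y_means, self.y_scales = normalize_columns(
                Y, center=True, scale=scale_columns
            )
        zc = Z - Z.mean()
        zsd = zc.std(ddof=1)
        if zsd == 0:
            raise ValueError("outcome Z is constant")
        # Z is normalized exactly like a data column (mean 0, unit variance),
        # so t'Z is on the same footing as any single column's contribution
        self.Z = zc / zsd
        self.z_mean, self.z_scale = float(Z.mean()), float(zsd)

    def fit(self) -> "SSMAResults":
        cfg = self.config
        Xd, Yd = self.X.copy(), self.Y.copy()
        rng = np.random.default_rng(cfg.seed)
        components = []
        for _ in range(cfg.n_components):
            lx, ly = cfg.lambda_x, cfg.lambda_y
            if lx == "auto" or ly == "auto":
                sel_lx, sel_ly = select_lambda(
                    Xd, Yd, self.Z, cfg.supervision,
                    grid_size=cfg.lambda_grid_size,
                    tol=cfg.tol, max_iter=cfg.max_iter,
                )
                lx = sel_lx if lx == "auto" else lx
                ly = sel_ly if ly == "auto" else ly
            comp = fit_component(
                Xd, Yd, self.Z, cfg.supervision, lx, ly,
                tol=cfg.tol, max_iter=cfg.max_iter,
                init=cfg.init, rng=rng,
            )
            Xd, comp.p_loading = deflate(Xd, comp.t)
            Yd, comp.q_loading = deflate(Yd, comp.u)
            components.append(comp)
        return SSMAResults(self, components)


class SSMAResults:
    """Fitted SSMA decomposition: weights, scores, loadings and diagnostics."""

    def __init__(self, model: SSMA, components: list):
        self.model = model
        self.components = components

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def weights_x(self) -> np.ndarray:
        """p x K matrix of sparse unit-norm predictor weights."""
        return np.column_stack([c.w_x for c in self.components])

    @property
    def weights_y(self) -> np.ndarray:
        return np.column_stack([c.w_y for c in self.components])

    @property
    def scores_t(self) -> np.ndarray:
        """n x K predictor scores (training subjects)."""
        return np.column_stack([c.t for c in self.components])

    @property
    def scores_u(self) -> np.ndarray:
        return np.column_stack([c.u for c in self.components])

    def transform(self, X_new, Y_new):
        """Scores (T, U) for new subjects, using the training normalization
        and the per-component weight/deflation sequence."""
        X_new = np.atleast_2d(np.asarray(X_new, float))
        Y_new = np.atleast_2d(np.asarray(Y_new, float))
        m = self.model
        if X_new.shape[1] != m.X.shape[1] or Y_new.shape[1] != m.Y.shape[1]:
            raise ValueError("new data column counts do not match training data")
        Xd = (X_new - m.x_means) / m.x_scales
        Yd = (Y_new - m.y_means) / m.y_scales
        T = np.empty((X_new.shape[0], self.n_components))
        U = np.empty((Y_new.shape[0], self.n_components))
        for k, comp in enumerate(self.components):
            T[:, k] = Xd @ comp.w_x
            U[:, k] = Yd @ comp.w_y
            Xd = Xd - np.outer(T[:, k], comp.p_loading)
            Yd = Yd - np.outer(U[:, k], comp.q_loading)
        return T, U

    def summary(self) -> str:
        """Plain-text per-component summary table."""
        sup = self.model.config.supervision
        lines = [
            "Supervised sparse multivariate analysis",
            f"  n = {self.model.X.shape[0]}, p = {self.model.X.shape[1]}, "
            f"q = {self.model.Y.shape[1]}, K = {self.n_components}",
            f"  supervision: mu_XY = {sup.mu_xy:.3f}, mu_XZ = {sup.mu_xz:.3f}, "
            f"mu_YZ = {sup.mu_yz:.3f}",
            "",
            f"{'comp':>4} {'lambda_x':>10} {'lambda_y':>10} {'nnz_x':>6} "
            f"{'nnz_y':>6} {'corr(t,u)':>10} {'corr(t,Z)':>10} {'corr(u,Z)':>10} "
            f"{'iters':>6} {'conv':>5}",
        ]
        Z = self.model.Z
        for k, c in enumerate(self.components, start=1):
            def corr(a, b):
                if a.std() == 0 or b.std() == 0:
                    return float("nan")
                return float(np.corrcoef(a, b)[0, 1])
            lines.append(
                f"{k:>4} {c.lambda_x:>10.4g} {c.lambda_y:>10.4g} "
                f"{np.count_nonzero(c.w_x):>6} {np.count_nonzero(c.w_y):>6} "
                f"{corr(c.t, c.u):>10.3f} {corr(c.t, Z):>10.3f} "
                f"{corr(c.u, Z):>10.3f} {c.n_iter:>6} {str(c.converged):>5}"
            )
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path):
        """Serialize the fitted model to ``path`` (.npz) + a JSON sidecar."""
        path = str(path)
        arrays = {
            "x_means": self.model.x_means, "x_scales": self.model.x_scales,
            "y_means": self.model.y_means, "y_scales": self.model.y_scales,
            "z_stats": np.array([self.model.z_mean, self.model.z_scale]),
        }
        for k, c in enumerate(self.components):
            arrays[f"w_x_{k}"] = c.w_x
            arrays[f"w_y_{k}"] = c.w_y
            arrays[f"t_{k}"] = c.t
            arrays[f"u_{k}"] = c.u
            arrays[f"p_{k}"] = c.p_loading
            arrays[f"q_{k}"] = c.q_loading
        np.savez_compressed(path, **arrays)
        cfg = self.model.config
        meta = {
            "n_components": self.n_components,
            "supervision": asdict(cfg.supervision),
            "lambda_grid_size": cfg.lambda_grid_size,
            "tol": cfg.tol, "max_iter": cfg.max_iter,
            "scale_columns": cfg.scale_columns, "init": cfg.init,
            "seed": cfg.seed,
            "components": [
                {
                    "lambda_x": c.lambda_x, "lambda_y": c.lambda_y,
                    "n_iter": c.n_iter, "converged": c.converged,
                    "nnz_x": int(np.count_nonzero(c.w_x)),
                    "nnz_y": int(np.count_nonzero(c.w_y)),
                }
                for c in self.components
            ],
        }
        stem = path[:-4] if path.endswith(".npz") else path
        with open(stem + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @staticmethod
    def load(path):
        """Load a saved archive into a lightweight transform-capable object."""
        return _LoadedSSMA(path)


class _LoadedSSMA:
    """Transform-only view of a serialized SSMA fit."""

    def __init__(self, path):
        path = str(path)
        if not path.endswith(".npz"):
            path = path + ".npz"
        with np.load(path) as arc:
            self.x_means = arc["x_means"]
            self.x_scales = arc["x_scales"]
            self.y_means = arc["y_means"]
            self.y_scales = arc["y_scales"]
            k = 0
            self.components = []
            while f"w_x_{k}" in arc:
                self.components.append(ComponentFit(
                    w_x=arc[f"w_x_{k}"], w_y=arc[f"w_y_{k}"],
                    t=arc[f"t_{k}"], u=arc[f"u_{k}"],
                    p_loading=arc[f"p_{k}"], q_loading=arc[f"q_{k}"],
                ))
                k += 1

    @property
    def n_components(self):
        return len(self.components)

    def transform(self, X_new, Y_new):
        X_new = np.atleast_2d(np.asarray(X_new, float))
        Y_new = np.atleast_2d(np.asarray(Y_new, float))
        Xd = (X_new - self.x_means) / self.x_scales
        Yd = (Y_new - self.y_means) / self.y_scales
        T = np.empty((X_new.shape[0], self.n_components))
        U = np.empty((Y_new.shape[0], self.n_components))
        for k, comp in enumerate(self.components):
            T[:, k] = Xd @ comp.w_x
            U[:, k] = Yd @ comp.w_y
            Xd = Xd - np.outer(T[:, k], comp.p_loading)
            Yd = Yd - np.outer(U[:, k], comp.q_loading)
        return T, U
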