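"""Radial B-spline basis expansion of voxelized images.

First dimension-reduction step: an n-subjects x N-voxels image stack is
projected onto q << N smooth radial cubic B-spline bumps centered at the
nodes of a regular knot lattice.  A fitted weight vector in basis space is
mapped back to voxel space as a *composite* basis function, the linear
combination of bumps that represents a spatial pattern.

Distances are measured in voxel units on 0-based integer voxel coordinates;
anisotropic voxel sizes are out of scope (physical-mm knot placement would
require the NIfTI affine).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "ImageStack",
    "KnotGrid",
    "BasisMatrix",
    "knot_distance",
    "radial_bspline_value",
    "make_knot_grid",
    "build_basis_matrix",
    "project_images",
    "composite_map",
]


@dataclass
class ImageStack:
    """A stack of vectorized images: one row per subject, one column per voxel.

    Parameters
    ----------
    data : (n, N) ndarray
        Vectorized images (C-order flattening of the grid), restricted to
        in-mask voxels when ``mask`` is given.
    grid_shape : tuple of int
        Shape of the underlying 2-D or 3-D voxel grid.
    voxel_coords : (N, d) int ndarray, optional
        0-based integer coordinates of each column's voxel.  Derived from
        ``grid_shape`` (and ``mask``) when omitted.
    mask : (prod(grid_shape),) bool ndarray, optional
        Analysis mask over the full grid; True = in analysis.
    """

    data: np.ndarray
    grid_shape: tuple
    voxel_coords: np.ndarray = None
    mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (subjects x voxels) array")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) not in (2, 3) or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 2 or 3 positive integers")
        n_grid = int(np.prod(self.grid_shape))
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool).ravel()
            if self.mask.size != n_grid:
                raise ValueError("mask length must equal prod(grid_shape)")
            if not self.mask.any():
                raise ValueError("mask selects no voxels")
            n_expected = int(self.mask.sum())
        else:
            n_expected = n_grid
        if self.data.shape[1] != n_expected:
            raise ValueError(
                f"data has {self.data.shape[1]} columns, expected {n_expected}"
            )
        if self.voxel_coords is None:
            full = np.indices(self.grid_shape).reshape(len(self.grid_shape), -1).T
            self.voxel_coords = full[self.mask] if self.mask is not None else full
        self.voxel_coords = np.asarray(self.voxel_coords)
        if self.voxel_coords.shape != (n_expected, len(self.grid_shape)):
            raise ValueError("voxel_coords shape inconsistent with data/grid")
        upper = np.asarray(self.grid_shape)
        if (self.voxel_coords < 0).any() or (self.voxel_coords >= upper).any():
            raise ValueError("voxel_coords out of grid bounds")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def ndim(self) -> int:
        return len(self.grid_shape)


@dataclass
class KnotGrid:
    """Regular lattice of radial-basis knots covering an image bounding box."""

    knots: np.ndarray          # (q, d) knot coordinates
    spacing: float             # lattice spacing in voxels
    h: float                   # knot distance = spacing * sqrt(d)
    ndim: int

    @property
    def n_knots(self) -> int:
        return self.knots.shape[0]


@dataclass
class BasisMatrix:
    """Sparse N x q design matrix of radial B-spline evaluations.

    ``col_map`` records, for each retained column, the index of the knot in
    ``knot_grid.knots`` it evaluates; all-zero columns (basis bumps with no
    in-mask support) are dropped at construction.
    """

    B: sparse.csr_matrix
    knot_grid: KnotGrid
    grid_shape: tuple
    col_map: np.ndarray = None

    def __post_init__(self):
        if self.col_map is None:
            self.col_map = np.arange(self.B.shape[1])

    @property
    def n_voxels(self) -> int:
        return self.B.shape[0]

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]


def knot_distance(spacing: float, ndim: int) -> float:
    """Distance h between diagonally adjacent knots of a regular lattice.

    h = spacing * sqrt(ndim): the body-diagonal step of the knot lattice,
    e.g. four-voxel spacing in 3-D gives h = sqrt(3 * 4^2) = 6.93.
    """
    if ndim not in (2, 3):
        raise ValueError(f"ndim must be 2 or 3, got {ndim}")
    spacing = float(spacing)
    if not spacing > 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    return spacing * math.sqrt(ndim)


def radial_bspline_value(dist, h: float):
    """Radial cubic B-spline profile phi(dist) with support radius 2h.

    With d = dist - h the value is piecewise cubic::

        (h^3 - 3 h^2 d + 3 h d^2 + 3 d^3) / (4 h^3)   d <= 0
        (h - d)^3 / (4 h^3)                           0 < d <= h
        0                                             d > h

    so phi(0) = 1 at the knot, phi(h) = 1/4, and phi vanishes beyond 2h,
    with continuous value, first and second derivative at the joins.
    Accepts scalars or arrays of distances.
    """
    h = float(h)
    if not h > 0:
        raise ValueError(f"h must be positive, got {h}")
    dist = np.asarray(dist, dtype=float)
    if (dist < 0).any():
        raise ValueError("distances must be nonnegative")
    d = dist - h
    inner = (h**3 - 3 * h**2 * d + 3 * h * d**2 + 3 * d**3) / (4 * h**3)
    outer = (h - d) ** 3 / (4 * h**3)
    out = np.where(d <= 0, inner, np.where(d <= h, outer, 0.0))
    return float(out) if out.ndim == 0 else out


def make_knot_grid(grid_shape, spacing: float, ndim: int = None) -> KnotGrid:
    """Place knots on a regular lattice with a one-spacing margin.

    Knots sit at integer multiples of ``spacing`` spanning
    [-spacing, extent - 1 + spacing] on every axis, so every voxel of the
    grid lies within 2h of at least one knot.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if ndim is None:
        ndim = len(grid_shape)
    if ndim != len(grid_shape):
        raise ValueError("ndim does not match grid_shape")
    if ndim not in (2, 3):
        raise ValueError("only 2-D and 3-D grids are supported")
    spacing = float(spacing)
    if spacing < 1:
        raise ValueError(f"spacing must be >= 1, got {spacing}")
    if spacing > min(grid_shape):
        raise ValueError(
            f"spacing {spacing} exceeds the smallest image extent {min(grid_shape)}"
        )
    axes = [
        np.arange(-spacing, (s - 1) + spacing + 1e-9, spacing) for s in grid_shape
    ]
    knots = np.array(list(itertools.product(*axes)), dtype=float)
    return KnotGrid(
        knots=knots, spacing=spacing, h=knot_distance(spacing, ndim), ndim=ndim
    )


def build_basis_matrix(stack: ImageStack, grid: KnotGrid) -> BasisMatrix:
    """Evaluate every basis bump at every in-mask voxel: B[j, k] = phi(||v_j - kappa_k||).

    Stored sparse (support radius 2h); columns with no in-mask support are
    dropped, with the surviving knot indices recorded in ``col_map``.
    """
    if grid.ndim != stack.ndim:
        raise ValueError("knot grid dimensionality does not match image stack")
    coords = stack.voxel_coords.astype(float)
    tree = cKDTree(grid.knots)
    # pairs (voxel, knot) within the 2h support radius
    dist_mat = tree.sparse_distance_matrix(
        cKDTree(coords), max_distance=2 * grid.h, output_type="coo_matrix"
    )
    # rows of dist_mat index knots, cols index voxels
    vals = radial_bspline_value(dist_mat.data, grid.h)
    B = sparse.coo_matrix(
        (vals, (dist_mat.col, dist_mat.row)),
        shape=(coords.shape[0], grid.n_knots),
    ).tocsc()
    B.eliminate_zeros()
    nonzero_cols = np.flatnonzero(np.diff(B.indptr) > 0)
    B = B[:, nonzero_cols].tocsr()
    return BasisMatrix(
        B=B, knot_grid=grid, grid_shape=stack.grid_shape, col_map=nonzero_cols
    )


def project_images(stack: ImageStack, basis: BasisMatrix) -> np.ndarray:
    """Project images onto the basis: the dense n x q coefficient matrix S B."""
    if stack.data.shape[1] != basis.B.shape[0]:
        raise ValueError(
            f"stack has {stack.data.shape[1]} voxels but basis expects {basis.B.shape[0]}"
        )
    return np.asarray(stack.data @ basis.B)


def composite_map(basis: BasisMatrix, w) -> np.ndarray:
    """Map basis-space weights back to voxel space: the composite function B w.

    Returns the N-vector over in-mask voxels (same column order as the
    originating :class:`ImageStack`).
    """
    w = np.asarray(w, dtype=float).ravel()
    if w.size != basis.B.shape[1]:
        raise ValueError(
            f"weight vector has length {w.size}, basis has {basis.B.shape[1]} columns"
        )
    return np.asarray(basis.B @ w)
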