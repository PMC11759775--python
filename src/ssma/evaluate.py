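"""Recovery scoring for simulation benchmarks.

Recovered weights are judged in pixel space: a fitted basis-space weight
vector is mapped through the composite basis function and every pixel with
a nonzero composite value counts as *selected*.  Selections are compared
with the binary ground-truth regions by the Youden-style index

    c-index = sensitivity - (1 - specificity),

which is 1 for perfect recovery, 0 in expectation for any uninformative
(random or select-everything) rule, and negative for anti-informative
selection.  Pixel-wise selection frequencies across simulation repetitions
give selection-probability maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisMatrix, composite_map

__all__ = ["CIndexRow", "ProbabilityMap", "binarize_weights", "c_index",
           "selection_probability_map", "score_correlation",
           "match_components"]


@dataclass(frozen=True)
class CIndexRow:
    sensitivity: float
    specificity: float

    @property
    def c_index(self) -> float:
        return self.sensitivity - (1.0 - self.specificity)


@dataclass(frozen=True)
class ProbabilityMap:
    """Pixel-wise selection frequency over simulation repetitions."""

    image: np.ndarray
    reps: int


def binarize_weights(basis: BasisMatrix, w, tol: float = 1e-10) -> np.ndarray:
    """Pixels whose composite-map magnitude exceeds ``tol``.

    The default tolerance separates structural zeros produced by
    soft-thresholding from floating-point residue.
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    return np.abs(composite_map(basis, w)) > tol


def c_index(selected, truth) -> CIndexRow:
    """Sensitivity/specificity of a binary selection against a binary truth."""
    selected = np.asarray(selected, bool).ravel()
    truth = np.asarray(truth, bool).ravel()
    if selected.size != truth.size:
        raise ValueError("selected and truth must have the same length")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain both positives and negatives")
    tp = int((selected & truth).sum())
    tn = int((~selected & ~truth).sum())
    return CIndexRow(sensitivity=tp / n_pos, specificity=tn / n_neg)


def selection_probability_map(masks) -> ProbabilityMap:
    """Pixel-wise mean of a nonempty list of equal-length binary masks."""
    masks = [np.asarray(m, bool).ravel() for m in masks]
    if not masks:
        raise ValueError("need at least one mask")
    if len({m.size for m in masks}) != 1:
        raise ValueError("masks must have equal lengths")
    return ProbabilityMap(
        image=np.mean(np.stack(masks).astype(float), axis=0), reps=len(masks)
    )


def score_correlation(T, U) -> np.ndarray:
    """Pearson correlations between every t-score and u-score column.

    Returns a K_T x K_U matrix; entries involving a constant column are NaN
    (undefined, reported as missing rather than 0).
    """
    T = np.atleast_2d(np.asarray(T, float))
    U = np.atleast_2d(np.asarray(U, float))
    if T.ndim != 2 or U.ndim != 2 or T.shape[0] != U.shape[0]:
        raise ValueError("T and U must be 2-D with equal row counts")
    if T.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    out = np.full((T.shape[1], U.shape[1]), np.nan)
    for i in range(T.shape[1]):
        ti = T[:, i]
        if ti.std() == 0:
            continue
        for j in range(U.shape[1]):
            uj = U[:, j]
            if uj.std() == 0:
                continue
            out[i, j] = np.corrcoef(ti, uj)[0, 1]
    return out


def match_components(sel_x, sel_y, s_x_true, s_y_true) -> list:
    """Greedily match fitted components to truth components.

    Component order after deflation is not identifiable, so estimated
    component ``perm[k]`` is paired with truth component ``k`` by greedy
    assignment on the mean signed c-index across the X and Y blocks (a
    single permutation shared by both blocks, since a component is common
    to them; signed, because only positive agreement indicates recovery).
    Returns ``perm`` with ``len == K_true``.
    """
    K_true = s_x_true.shape[1]
    K_est = len(sel_x)
    score = np.zeros((K_est, K_true))
    for i in range(K_est):
        for k in range(K_true):
            cx = c_index(sel_x[i], s_x_true[:, k]).c_index
            cy = c_index(sel_y[i], s_y_true[:, k]).c_index
            score[i, k] = (cx + cy) / 2
    perm = [-1] * K_true
    used = set()
    # greedy: repeatedly take the best remaining (estimate, truth) pair
    flat = sorted(
        ((score[i, k], i, k) for i in range(K_est) for k in range(K_true)),
        reverse=True,
    )
    assigned = set()
    for s, i, k in flat:
        if i in used or k in assigned:
            continue
        perm[k] = i
        used.add(i)
        assigned.add(k)
    if any(p < 0 for p in perm):
        raise ValueError("fewer estimated components than truth components")
    return perm
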