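"""File I/O: NIfTI image stacks, composite-map volumes, and dataset export.

2-D simulated images are persisted as single-slice 3-D NIfTI volumes so the
same reader path serves simulated and real workflows.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .basis import ImageStack, BasisMatrix, composite_map

__all__ = [
    "load_image_stack",
    "save_composite_map",
    "save_probability_map",
    "export_simdata",
    "load_outcome_csv",
]


def _squeeze_shape(shape):
    """Drop trailing singleton axes (single-slice 3-D -> 2-D grid)."""
    shape = tuple(int(s) for s in shape)
    while len(shape) > 2 and shape[-1] == 1:
        shape = shape[:-1]
    return shape


def load_image_stack(paths, mask_path=None) -> tuple:
    """Read one NIfTI volume per subject into an :class:`ImageStack`.

    All volumes must share a grid shape (and should share an affine); the
    optional mask volume restricts analysis to its nonzero voxels.  Returns
    (stack, reference_image) where the reference is the first subject's
    nibabel image, reused for writing result maps.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("need at least one image path")
    ref = nib.load(str(paths[0]))
    shape = _squeeze_shape(ref.shape)
    mask = None
    if mask_path is not None:
        m_img = nib.load(str(mask_path))
        if _squeeze_shape(m_img.shape) != shape:
            raise ValueError("mask shape does not match the image shape")
        mask = np.asarray(m_img.get_fdata()).reshape(-1) > 0
    rows = []
    for p in paths:
        img = nib.load(str(p))
        if _squeeze_shape(img.shape) != shape:
            raise ValueError(f"{p} has shape {img.shape}, expected {shape}")
        vec = np.asarray(img.get_fdata(), dtype=float).reshape(-1)
        rows.append(vec[mask] if mask is not None else vec)
    return ImageStack(np.vstack(rows), shape, mask=mask), ref


def _to_volume(values, grid_shape, mask=None):
    full = np.zeros(int(np.prod(grid_shape)))
    if mask is not None:
        full[mask] = values
    else:
        full[:] = values
    vol = full.reshape(grid_shape)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    return vol


def save_composite_map(path, basis: BasisMatrix, w, reference=None, mask=None):
    """Write the composite map of a weight vector as a NIfTI volume."""
    vol = _to_volume(composite_map(basis, w), basis.grid_shape, mask)
    affine = reference.affine if reference is not None else np.eye(4)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))


def save_probability_map(path, image, grid_shape, reference=None, mask=None):
    """Write a pixel-wise selection-probability image as NIfTI."""
    vol = _to_volume(np.asarray(image, float), grid_shape, mask)
    affine = reference.affine if reference is not None else np.eye(4)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))


def load_outcome_csv(path, column=None) -> np.ndarray:
    """Read the outcome vector Z from a CSV (first numeric column by default)."""
    df = pd.read_csv(path)
    if column is None:
        numeric = df.select_dtypes("number")
        if numeric.shape[1] == 0:
            raise ValueError(f"{path} has no numeric column")
        return numeric.iloc[:, 0].to_numpy(float)
    return df[column].to_numpy(float)


def export_simdata(data, out_dir, force: bool = False):
    """Write a simulated dataset to ``out_dir``.

    Per-subject X and Y NIfTI volumes, Z and latent scores as CSV, binary
    truth masks as NIfTI, and the generating configuration as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_path = out / "config.json"
    if cfg_path.exists() and not force:
        raise FileExistsError(f"{cfg_path} exists; pass force=True to overwrite")
    shape = data.config.image_shape
    affine = np.eye(4)
    for block, mat in (("X", data.X), ("Y", data.Y)):
        d = out / block
        d.mkdir(exist_ok=True)
        for i, row in enumerate(mat):
            vol = _to_volume(row, shape)
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                     str(d / f"subj{i:03d}.nii"))
    for block, truth in (("X", data.s_x_true), ("Y", data.s_y_true)):
        for k in range(truth.shape[1]):
            vol = _to_volume(truth[:, k].astype(float), shape)
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                     str(out / f"truth_{block}_comp{k + 1}.nii"))
    pd.DataFrame({"Z": data.Z}).to_csv(out / "Z.csv", index=False)
    scores = {}
    for k in range(data.t_true.shape[1]):
        scores[f"t{k + 1}"] = data.t_true[:, k]
        scores[f"u{k + 1}"] = data.u_true[:, k]
    pd.DataFrame(scores).to_csv(out / "latent_scores.csv", index=False)
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(data.config).items()}
    cfg_path.write_text(json.dumps(cfg, indent=2))
    return out
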