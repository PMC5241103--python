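"""NIfTI reading/writing for scalar maps and masks.

The on-disk convention: masks are uint8 0/1 volumes; scalar maps are
float64 with invalid voxels stored as NaN (validity is reconstructed as
``isfinite`` on read). The affine must encode positive spacing and an
axis-aligned orientation; volumes whose header differs are reoriented to
the closest canonical (RAS) orientation on load.
"""

from __future__ import annotations

import os
from typing import Union

import nibabel as nib
import numpy as np

from .grids import Mask, ScalarMap, VolumeGrid

__all__ = ["read_volume", "write_volume", "grid_from_affine"]


def grid_from_affine(shape, affine) -> VolumeGrid:
    """Build a VolumeGrid from a NIfTI affine, rejecting oblique headers."""
    rot = np.asarray(affine)[:3, :3]
    spacing = np.sqrt((rot ** 2).sum(axis=0))
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ValueError(f"non-positive or non-finite spacing in affine: {spacing}")
    # axis-aligned check: off-diagonal terms negligible relative to spacing
    off = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off)) > 1e-3 * np.max(spacing):
        raise ValueError(
            "oblique affine: this package enforces axis-aligned, right-handed "
            "grids; reorient/resample the volume before loading"
        )
    if np.any(np.diag(rot) <= 0):
        raise ValueError("negative axis direction after canonical reorientation")
    origin = np.asarray(affine)[:3, 3]
    return VolumeGrid(tuple(int(s) for s in shape),
                      tuple(float(s) for s in np.diag(rot)),
                      tuple(float(o) for o in origin))


def _looks_like_mask(data: np.ndarray) -> bool:
    finite = data[np.isfinite(data)]
    if finite.size == 0:
        return False
    u = np.unique(finite)
    return u.size <= 2 and np.all(np.isin(u, (0.0, 1.0)))


def read_volume(path: Union[str, os.PathLike], as_mask: bool | None = None,
                label: str = "") -> Union[ScalarMap, Mask]:
    """Read a NIfTI volume as a :class:`ScalarMap` or :class:`Mask`.

    Masks are detected by integer 0/1 content unless ``as_mask`` forces the
    interpretation. Non-3D volumes and non-positive spacings are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D volume, got shape {img.shape}: {path}")
    img = nib.as_closest_canonical(img)
    grid = grid_from_affine(img.shape, img.affine)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if as_mask is None:
        as_mask = _looks_like_mask(data)
    if as_mask:
        return Mask(grid, np.nan_to_num(data) > 0.5, label or os.path.basename(str(path)))
    valid = np.isfinite(data)
    values = np.where(valid, data, 0.0)
    # keep NaN semantics out of the values array; validity carries the flag
    return ScalarMap(grid, values, unit="arbitrary-signal", valid=valid)


def write_volume(v: Union[ScalarMap, Mask], path: Union[str, os.PathLike]) -> None:
    """Write a volume as NIfTI; spacing/origin round-trip via the affine."""
    grid = v.grid
    if isinstance(v, Mask):
        data = v.data.astype(np.uint8)
    else:
        data = np.where(v.valid, v.values, np.nan).astype(np.float64)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(grid.spacing)
    d = os.path.dirname(str(path))
    if d and not os.path.isdir(d):
        raise IOError(f"directory does not exist: {d}")
    nib.save(img, str(path))
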