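"""Metabolite-map standardization: ratios, NAWM reference, fold-normal maps.

Raw spectroscopic metabolite signal is in arbitrary units that drift with
age, coil loading and brain region, so maps are standardized by dividing
by the mean value in contralateral normal-appearing white matter (NAWM):
the result is a *fold-normal* map in which 1.0 means "like healthy white
matter" and 2.0 means a two-fold elevation. Fold-normal Cho/NAA maps are
then thresholded (1.5-, 1.75-, 2.0-fold by convention) to delineate
metabolic abnormality for target planning.

By default the Cho/NAA *ratio* is normalized by the NAWM mean ratio.
Normalizing Cho and NAA individually before ratioing is mathematically
different (the mean of a quotient is not the quotient of means); both
paths are available through :func:`fold_cho_naa`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .grids import GridMismatchError, Mask, ScalarMap, _require_same_grid

__all__ = [
    "FoldMap",
    "ratio_map",
    "segment_nawm",
    "normalize_fold",
    "fold_cho_naa",
    "threshold_segmentation",
]


@dataclass
class FoldMap:
    """A ScalarMap standardized so that its mean over the reference
    region is 1.0, together with the reference provenance."""

    map: ScalarMap
    reference_mean: float
    reference_label: str = "NAWM"
    reference_count: int = 0

    @property
    def grid(self):
        return self.map.grid

    @property
    def values(self):
        return self.map.values

    @property
    def valid(self):
        return self.map.valid


def ratio_map(cho: ScalarMap, naa: ScalarMap, naa_floor: float = 1e-6) -> ScalarMap:
    """Voxelwise Cho/NAA ratio.

    Voxels where either input is invalid or NAA <= ``naa_floor`` are
    flagged invalid, never clipped to a large number.
    """
    _require_same_grid(cho, naa, "ratio_map")
    valid = cho.valid & naa.valid & (naa.values > naa_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(valid, cho.values / np.where(valid, naa.values, 1.0), 0.0)
    return ScalarMap(cho.grid, vals, "arbitrary-signal", valid)


def segment_nawm(
    wm_prob: ScalarMap,
    hemispheres: np.ndarray,
    tumor_side: int,
    exclusions: Sequence[Mask] = (),
    p_min: float = 0.9,
    exclusion_margin_mm: float = 10.0,
    min_volume_cm3: float = 10.0,
) -> Mask:
    """Contralateral normal-appearing white matter reference region.

    NAWM = {wm_prob >= p_min} within the hemisphere opposite the tumor,
    minus every exclusion mask dilated by a metric safety margin. Refuses
    (raises ``ValueError``) if the region falls below ``min_volume_cm3``
    — too small a reference makes the normalization untrustworthy.
    """
    grid = wm_prob.grid
    hemispheres = np.asarray(hemispheres)
    if hemispheres.shape != grid.shape:
        raise GridMismatchError("hemisphere labels not on the white-matter grid")
    contra = hemispheres > 0
    contra &= hemispheres != tumor_side
    sel = (wm_prob.values >= p_min) & wm_prob.valid & contra
    for ex in exclusions:
        _require_same_grid(wm_prob, ex, "segment_nawm")
        grown = ex.data
        if exclusion_margin_mm > 0 and ex.data.any():
            d = ndimage.distance_transform_edt(~ex.data, sampling=grid.spacing)
            grown = d <= exclusion_margin_mm
        sel &= ~grown
    nawm = Mask(grid, sel, "NAWM")
    if nawm.volume_cm3 < min_volume_cm3:
        raise ValueError(
            f"NAWM reference region is {nawm.volume_cm3:.2f} cm3 "
            f"(< {min_volume_cm3} cm3 minimum); refusing to normalize"
        )
    return nawm


def normalize_fold(m: ScalarMap | FoldMap, nawm: Mask,
                   min_valid_fraction: float = 0.95) -> FoldMap:
    """Standardize a map by its mean over NAWM (fold-normal scaling).

    The output equals ``m / mean(m over nawm & valid)``; the reference
    mean is recorded in the returned :class:`FoldMap`. Errors if the map
    is invalid on more than ``1 - min_valid_fraction`` of NAWM or the
    reference mean is non-positive. Idempotent: renormalizing a FoldMap
    by the same NAWM returns it unchanged to machine precision.
    """
    if isinstance(m, FoldMap):
        m = m.map
    _require_same_grid(m, nawm, "normalize_fold")
    if nawm.is_empty:
        raise ValueError("empty NAWM reference region")
    in_ref = nawm.data
    ok = in_ref & m.valid
    frac = ok.sum() / in_ref.sum()
    if frac < min_valid_fraction:
        raise ValueError(
            f"map valid on only {100 * frac:.1f}% of NAWM "
            f"(< {100 * min_valid_fraction:.0f}% required)"
        )
    ref = float(m.values[ok].mean())
    if ref <= 0:
        raise ValueError(f"non-positive NAWM reference mean ({ref:g})")
    out = ScalarMap(m.grid, np.where(m.valid, m.values / ref, 0.0),
                    "fold-normal", m.valid.copy())
    return FoldMap(out, reference_mean=ref, reference_label=nawm.label or "NAWM",
                   reference_count=int(ok.sum()))


def fold_cho_naa(cho: ScalarMap, naa: ScalarMap, nawm: Mask,
                 mode: str = "ratio-first", naa_floor: float = 1e-6) -> FoldMap:
    """Fold-normal Cho/NAA map, by either normalization order.

    mode='ratio-first' (default): compute Cho/NAA, then scale by the NAWM
    mean *ratio*. mode='separate': scale Cho and NAA each by their own
    NAWM mean, then ratio the standardized maps. The two differ whenever
    Cho and NAA covary within NAWM.
    """
    if mode == "ratio-first":
        return normalize_fold(ratio_map(cho, naa, naa_floor), nawm)
    if mode == "separate":
        cho_f = normalize_fold(cho, nawm)
        naa_f = normalize_fold(naa, nawm)
        ratio = ratio_map(cho_f.map, naa_f.map, naa_floor / max(naa_f.reference_mean, 1e-300))
        ratio.unit = "fold-normal"
        return FoldMap(ratio, reference_mean=cho_f.reference_mean / naa_f.reference_mean,
                       reference_label=nawm.label or "NAWM",
                       reference_count=cho_f.reference_count)
    raise ValueError(f"unknown mode {mode!r}")


def threshold_segmentation(f: FoldMap, level: float, brain: Mask,
                           keep_touching: Optional[Mask] = None) -> Mask:
    """Segment the metabolic abnormality at a fold threshold.

    mask = {fold >= level} within the brain and the map's validity
    support. The comparison is closed (>=), the conservative choice that
    yields the larger target. No connected-component filtering happens by
    default; pass ``keep_touching`` (typically GTV2) to retain only
    components intersecting that mask.
    """
    if level <= 0:
        raise ValueError("threshold level must be positive")
    _require_same_grid(f.map, brain, "threshold_segmentation")
    sel = (f.values >= level) & f.valid & brain.data
    if keep_touching is not None and sel.any():
        _require_same_grid(f.map, keep_touching, "threshold_segmentation")
        labels, n = ndimage.label(sel)
        keep_ids = np.unique(labels[keep_touching.data & (labels > 0)])
        sel = np.isin(labels, keep_ids) & (labels > 0)
    return Mask(brain.grid, sel, f"choNAA_fold{level:g}")
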