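"""Volumetric, spatial, dosimetric and recurrence-coverage metrics.

Every binary metric requires both volumes on the same grid — cross-grid
comparison must go through an explicit resampling step, never an
implicit one, because silent resampling is the classic source of
irreproducible overlap numbers. Dose maxima use the point-max
convention (the hottest voxel, no D0.03cc smoothing) and isodose
membership uses the closed comparison (dose >= level).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .grids import Mask, ScalarMap, _require_same_grid
from .targets import PlanConfig, PlanVolumes

__all__ = [
    "dice", "volume_cm3", "percent_increase", "isodose_mask", "volume_outside",
    "coverage_percent", "max_dose_in", "recurrence_coverage", "evaluate_plan",
    "ComparisonRecord",
]

log = logging.getLogger(__name__)


def dice(a: Mask, b: Mask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks agree perfectly by convention: Dice = 1.0 (logged).
    """
    _require_same_grid(a, b, "dice")
    na, nb = a.count, b.count
    if na + nb == 0:
        log.info("dice of two empty masks: returning 1.0 by convention")
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def volume_cm3(m: Mask) -> float:
    """Mask volume in cm3 (member count x voxel volume)."""
    return m.volume_cm3


def percent_increase(base: Mask, new: Mask) -> float:
    """100 * (vol(new) - vol(base)) / vol(base); errors on empty base."""
    _require_same_grid(base, new, "percent_increase")
    vb = base.volume_cm3
    if vb == 0:
        raise ValueError("percent_increase undefined for an empty base mask")
    return 100.0 * (new.volume_cm3 - vb) / vb


def isodose_mask(dose: ScalarMap, level_gy: float) -> Mask:
    """Voxels receiving at least ``level_gy`` (closed comparison)."""
    return Mask(dose.grid, dose.values >= level_gy, f"IDL{level_gy:g}")


def volume_outside(seg: Mask, region: Mask) -> Tuple[float, float]:
    """(cm3, percent) of ``seg`` extending beyond ``region``.

    An empty segmentation returns (0, 0) with a warning — there is
    nothing to escape.
    """
    _require_same_grid(seg, region, "volume_outside")
    n_seg = seg.count
    if n_seg == 0:
        warnings.warn("volume_outside of an empty segmentation is (0, 0)",
                      stacklevel=2)
        return 0.0, 0.0
    n_out = int((seg.data & ~region.data).sum())
    return n_out * seg.grid.voxel_volume_cm3, 100.0 * n_out / n_seg


def coverage_percent(target: Mask, dose: ScalarMap, level_gy: float) -> float:
    """Percent of target voxels receiving at least ``level_gy``."""
    _require_same_grid(target, dose, "coverage_percent")
    n = target.count
    if n == 0:
        raise ValueError("coverage undefined for an empty target")
    covered = int((target.data & (dose.values >= level_gy)).sum())
    return 100.0 * covered / n


def max_dose_in(organ: Mask, dose: ScalarMap) -> float:
    """Maximum point dose (Gy) over the organ's voxels."""
    _require_same_grid(organ, dose, "max_dose_in")
    if organ.is_empty:
        raise ValueError("max dose undefined for an empty organ")
    return float(dose.values[organ.data].max())


def recurrence_coverage(rec: Mask, ctv: Mask) -> float:
    """Percent of the recurrent tumor contained in a target volume."""
    _require_same_grid(rec, ctv, "recurrence_coverage")
    n = rec.count
    if n == 0:
        raise ValueError("recurrence coverage undefined for an empty recurrence")
    return 100.0 * int((rec.data & ctv.data).sum()) / n


@dataclass
class ComparisonRecord:
    """One plan-evaluation row (one patient, one threshold or conventional)."""

    patient_id: str = ""
    threshold: Optional[float] = None   # None for the conventional plan
    vol_ctv2_cm3: float = np.nan
    vol_smri_ctv2_cm3: float = np.nan
    vol_seg_cm3: float = np.nan
    pct_increase_ctv2: float = np.nan
    pct_increase_ctv1: float = np.nan
    dice_ctv2: float = np.nan
    seg_outside_ctv1_cm3: float = np.nan
    seg_outside_ctv1_pct: float = np.nan
    seg_outside_ctv2_cm3: float = np.nan
    seg_outside_ctv2_pct: float = np.nan
    seg_outside_idl1_cm3: float = np.nan
    seg_outside_idl1_pct: float = np.nan
    seg_outside_idl2_cm3: float = np.nan
    seg_outside_idl2_pct: float = np.nan
    coverage_ptv1_pct: float = np.nan
    coverage_ptv2_pct: float = np.nan
    brainstem_max_gy: float = np.nan
    recurrence_cov_ctv_pct: float = np.nan
    recurrence_cov_57gy_pct: float = np.nan
    recurrence_cov_60gy_pct: float = np.nan
    violations: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["violations"] = ";".join(self.violations)
        return d


def evaluate_plan(
    pv: PlanVolumes,
    dose: ScalarMap,
    organs: Optional[Dict[str, Mask]] = None,
    rec: Optional[Mask] = None,
    cfg: PlanConfig = PlanConfig(),
    patient_id: str = "",
    threshold: Optional[float] = None,
    conventional_dose: Optional[ScalarMap] = None,
) -> ComparisonRecord:
    """Populate a :class:`ComparisonRecord` for one plan.

    Uses the sMRI chain (sMRI_CTV/PTV) when present, the conventional one
    otherwise. Escape volumes of the Cho/NAA segmentation are measured
    against CTV1/CTV2 and the *conventional* prescription isodose regions
    (pass ``conventional_dose``; defaults to ``dose``). Constraint
    violations (target coverage goal, brainstem soft/hard limits) are
    flagged in ``record.violations``.
    """
    organs = organs or {}
    rec_row = ComparisonRecord(patient_id=patient_id, threshold=threshold)

    ctv1, ctv2 = pv["CTV1"], pv["CTV2"]
    smri = "sMRI_CTV2" in pv
    ptv1 = pv["sMRI_PTV1"] if smri else pv["PTV1"]
    ptv2 = pv["sMRI_PTV2"] if smri else pv["PTV2"]
    ref_dose = conventional_dose if conventional_dose is not None else dose

    rec_row.vol_ctv2_cm3 = volume_cm3(ctv2)
    if smri:
        seg = pv["choNAA_seg"]
        rec_row.vol_smri_ctv2_cm3 = volume_cm3(pv["sMRI_CTV2"])
        rec_row.vol_seg_cm3 = volume_cm3(seg)
        rec_row.pct_increase_ctv2 = percent_increase(ctv2, pv["sMRI_CTV2"])
        rec_row.pct_increase_ctv1 = percent_increase(ctv1, pv["sMRI_CTV1"])
        rec_row.dice_ctv2 = dice(ctv2, seg)
        rec_row.seg_outside_ctv1_cm3, rec_row.seg_outside_ctv1_pct = \
            volume_outside(seg, ctv1)
        rec_row.seg_outside_ctv2_cm3, rec_row.seg_outside_ctv2_pct = \
            volume_outside(seg, ctv2)
        idl1 = isodose_mask(ref_dose, cfg.rx_ptv1_gy)
        idl2 = isodose_mask(ref_dose, cfg.rx_ptv2_gy)
        rec_row.seg_outside_idl1_cm3, rec_row.seg_outside_idl1_pct = \
            volume_outside(seg, idl1)
        rec_row.seg_outside_idl2_cm3, rec_row.seg_outside_idl2_pct = \
            volume_outside(seg, idl2)

    rec_row.coverage_ptv1_pct = coverage_percent(ptv1, dose, cfg.rx_ptv1_gy)
    rec_row.coverage_ptv2_pct = coverage_percent(ptv2, dose, cfg.rx_ptv2_gy)
    if rec_row.coverage_ptv1_pct < cfg.coverage_goal_pct:
        rec_row.violations.append(
            f"PTV1 coverage {rec_row.coverage_ptv1_pct:.1f}% < "
            f"{cfg.coverage_goal_pct:g}% goal")
    if rec_row.coverage_ptv2_pct < cfg.relaxed_ptv2_coverage_pct:
        rec_row.violations.append(
            f"PTV2 coverage {rec_row.coverage_ptv2_pct:.1f}% < "
            f"{cfg.relaxed_ptv2_coverage_pct:g}% relaxed floor")

    if "brainstem" in organs:
        bs = organs["brainstem"]
        rec_row.brainstem_max_gy = max_dose_in(bs, dose)
        if rec_row.brainstem_max_gy > cfg.brainstem_hard_max_gy:
            rec_row.violations.append(
                f"brainstem max {rec_row.brainstem_max_gy:.1f} Gy > "
                f"{cfg.brainstem_hard_max_gy:g} Gy hard limit")
        above_soft = 100.0 * int((bs.data & (dose.values > cfg.oar_soft_max_gy)).sum()) \
            / max(bs.count, 1)
        if above_soft > cfg.brainstem_above_soft_pct:
            rec_row.violations.append(
                f"{above_soft:.1f}% of brainstem above {cfg.oar_soft_max_gy:g} Gy "
                f"(> {cfg.brainstem_above_soft_pct:g}% allowed)")

    if rec is not None and not rec.is_empty:
        cov_ctv = recurrence_coverage(rec, pv["sMRI_CTV2"] if smri else ctv2)
        rec_row.recurrence_cov_ctv_pct = cov_ctv
        rec_row.recurrence_cov_57gy_pct = coverage_percent(rec, dose, 57.0)
        rec_row.recurrence_cov_60gy_pct = coverage_percent(rec, dose, cfg.rx_ptv2_gy)

    return rec_row
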