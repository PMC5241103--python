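"""Radiotherapy target-volume construction.

Conventional glioblastoma planning uses two nested target chains built
from clinician-drawn gross volumes: GTV1 (the T2/FLAIR abnormality) and
GTV2 (contrast enhancement plus the resection cavity). Clinical target
volumes add metric margins for microscopic spread — 7 mm around GTV1,
5 mm around GTV2 — clipped to the brain's external contour (tumor does
not spread through bone), and planning target volumes add a further 3 mm
setup-uncertainty margin that is *not* clipped. The spectroscopically
modified chain merges a Cho/NAA threshold segmentation into CTV2
(sMRI_CTV2 = CTV2 union segmentation), merges that with CTV1 for the
low-dose chain, and re-applies the 3 mm PTV margin.

Margins are true Euclidean distances computed with an anisotropic-aware
distance transform, never an isotropic structuring element: at 5.6 mm
slice spacing a voxel-ball dilation is wrong by up to a slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import GridMismatchError, Mask, _require_same_grid

__all__ = ["PlanConfig", "PlanVolumes", "expand_margin", "build_conventional",
           "build_smri"]


@dataclass(frozen=True)
class PlanConfig:
    """Margins, thresholds, prescriptions and constraints for one plan."""

    ctv1_margin_mm: float = 7.0
    ctv2_margin_mm: float = 5.0
    ptv_margin_mm: float = 3.0
    fold_thresholds: Tuple[float, ...] = (1.5, 1.75, 2.0)
    rx_ptv1_gy: float = 51.0          # 54 Gy for one patient in the source cohort
    rx_ptv2_gy: float = 60.0
    fractions: int = 30
    oar_soft_max_gy: float = 54.0     # brainstem / optic structures, soft
    brainstem_hard_max_gy: float = 60.0
    brainstem_above_soft_pct: float = 10.0  # <=10% of brainstem above 54 Gy
    coverage_goal_pct: float = 95.0   # 100% of dose to 95% of target
    relaxed_ptv2_coverage_pct: float = 90.0
    penumbra_mm: float = 5.0

    def __post_init__(self):
        if min(self.ctv1_margin_mm, self.ctv2_margin_mm, self.ptv_margin_mm) < 0:
            raise ValueError("margins must be >= 0")
        th = tuple(self.fold_thresholds)
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("fold thresholds must be strictly increasing")
        if self.rx_ptv1_gy <= 0 or self.rx_ptv2_gy <= 0:
            raise ValueError("prescriptions must be positive")


@dataclass
class PlanVolumes:
    """Named plan masks plus a provenance log of how each was built."""

    masks: Dict[str, Mask] = field(default_factory=dict)
    provenance: List[dict] = field(default_factory=list)

    def __getitem__(self, name: str) -> Mask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def add(self, name: str, mask: Mask, **prov) -> None:
        self.masks[name] = mask.copy(label=name)
        self.provenance.append({"structure": name, **prov})

    def copy(self) -> "PlanVolumes":
        pv = PlanVolumes()
        pv.masks = {k: v.copy() for k, v in self.masks.items()}
        pv.provenance = [dict(p) for p in self.provenance]
        return pv


def expand_margin(m: Mask, margin_mm: float, barrier: Optional[Mask] = None,
                  label: str = "") -> Mask:
    """Expand a mask by a metric margin under anisotropic spacing.

    The result is every voxel whose center lies within ``margin_mm``
    (world-mm Euclidean distance) of a member voxel center, optionally
    intersected with a barrier mask (e.g. the brain external contour).
    Expansion by 0 is the identity; the input is always a subset of the
    output (before barrier clipping the operation is extensive).
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if margin_mm == 0 or m.is_empty:
        out = m.data.copy()
    else:
        d = ndimage.distance_transform_edt(~m.data, sampling=m.grid.spacing)
        out = d <= margin_mm + 1e-9
    if barrier is not None:
        _require_same_grid(m, barrier, "expand_margin barrier")
        out &= barrier.data
    return Mask(m.grid, out, label or m.label)


def build_conventional(gtv1: Mask, gtv2: Mask, brain: Mask,
                       cfg: PlanConfig = PlanConfig()) -> PlanVolumes:
    """Conventional GTV -> CTV -> PTV chains.

    CTVs are margin expansions clipped to the brain; PTVs add the setup
    margin unclipped. GTV2 exceeding GTV1 is pathological but permitted
    (logged as a warning); empty GTVs are an error.
    """
    for g in (gtv1, gtv2):
        _require_same_grid(g, brain, "build_conventional")
        if g.is_empty:
            raise ValueError(f"empty gross target volume {g.label!r}")
    if not gtv2.issubset(gtv1):
        warnings.warn("GTV2 (enhancement) extends beyond GTV1 (FLAIR); "
                      "proceeding, but check the input contours", stacklevel=2)

    pv = PlanVolumes()
    pv.add("GTV1", gtv1, source="input")
    pv.add("GTV2", gtv2, source="input")
    ctv1 = expand_margin(gtv1, cfg.ctv1_margin_mm, barrier=brain, label="CTV1")
    ctv2 = expand_margin(gtv2, cfg.ctv2_margin_mm, barrier=brain, label="CTV2")
    pv.add("CTV1", ctv1, source="GTV1", margin_mm=cfg.ctv1_margin_mm, barrier="brain")
    pv.add("CTV2", ctv2, source="GTV2", margin_mm=cfg.ctv2_margin_mm, barrier="brain")
    pv.add("PTV1", expand_margin(ctv1, cfg.ptv_margin_mm, label="PTV1"),
           source="CTV1", margin_mm=cfg.ptv_margin_mm, barrier=None)
    pv.add("PTV2", expand_margin(ctv2, cfg.ptv_margin_mm, label="PTV2"),
           source="CTV2", margin_mm=cfg.ptv_margin_mm, barrier=None)
    return pv


def build_smri(pv: PlanVolumes, cho_naa_seg: Mask,
               cfg: PlanConfig = PlanConfig()) -> PlanVolumes:
    """Merge a Cho/NAA threshold segmentation into the plan.

    sMRI_CTV2 = CTV2 union segmentation; sMRI_CTV1 = sMRI_CTV2 union
    CTV1; each sMRI_PTV adds the setup margin. The union construction
    guarantees no conventionally targeted voxel is ever dropped
    (CTV2 is always a subset of sMRI_CTV2).
    """
    for name in ("CTV1", "CTV2"):
        if name not in pv:
            raise ValueError(f"plan volumes lack {name}; build_conventional first")
    _require_same_grid(pv["CTV2"], cho_naa_seg, "build_smri")

    out = pv.copy()
    seg_label = cho_naa_seg.label or "choNAA_seg"
    smri_ctv2 = pv["CTV2"].union(cho_naa_seg, "sMRI_CTV2")
    smri_ctv1 = smri_ctv2.union(pv["CTV1"], "sMRI_CTV1")
    out.add("choNAA_seg", cho_naa_seg, source="threshold_segmentation")
    out.add("sMRI_CTV2", smri_ctv2, source=f"CTV2 | {seg_label}")
    out.add("sMRI_PTV2", expand_margin(smri_ctv2, cfg.ptv_margin_mm),
            source="sMRI_CTV2", margin_mm=cfg.ptv_margin_mm)
    out.add("sMRI_CTV1", smri_ctv1, source=f"sMRI_CTV2 | CTV1")
    out.add("sMRI_PTV1", expand_margin(smri_ctv1, cfg.ptv_margin_mm),
            source="sMRI_CTV1", margin_mm=cfg.ptv_margin_mm)
    return out
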