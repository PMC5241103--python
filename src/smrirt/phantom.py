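"""Synthetic glioblastoma "patient" generator.

Produces everything a downstream planning analysis needs with known
ground truth: an ellipsoidal brain split into hemispheres, a deep
white-matter shell, nested tumor compartments (cavity < enhancing core <
FLAIR abnormality), a continuous metabolic-infiltration field extending
beyond the enhancing core, Cho and NAA maps sampled on the coarse
spectroscopic grid, conformal dose surrogates, and recurrence masks
biased toward the pre-treatment metabolic abnormality.

The infiltration field is

    f(x) = A * exp(-d(x)^2 / sigma_inf^2)

where ``d(x)`` is the world-mm distance outside the enhancing core
(``f = A`` inside the core, 0 outside the brain). The Cho/NAA ratio is
``baseline * (1 + f) * eps`` with unit-mean multiplicative lognormal
noise ``eps`` of coefficient of variation ``noise_cv``; choline is
elevated and NAA suppressed toward the core so that their voxelwise
quotient reproduces this field exactly. The field is sampled at the
coarse spectroscopic voxel centers — reaching the clinical grid requires
the same trilinear upsampling step real data undergo, which is where the
partial-volume behaviour the analysis must tolerate comes from.

Doses are a parametric conformal surrogate for an inverse-planned
treatment: full prescription inside each target, logistic falloff with
distance outside, combined across targets by voxelwise maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import Mask, ScalarMap, VolumeGrid

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "generate_phantom",
    "generate_dose",
    "generate_recurrence",
    "analytic_threshold_radius",
]


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic patient.

    Defaults are the reduced profile (120^3 voxels at 1.5 mm, a 180 mm
    box) used throughout testing; a full-size ~1 mm clinical grid is a
    configuration away. All lengths in mm.
    """

    clinical_shape: Tuple[int, int, int] = (120, 120, 120)
    clinical_spacing: Tuple[float, float, float] = (1.5, 1.5, 1.5)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    smri_spacing: Tuple[float, float, float] = (4.4, 4.4, 5.6)

    brain_center: Optional[Tuple[float, float, float]] = None  # default: box center
    brain_semiaxes: Tuple[float, float, float] = (70.0, 80.0, 65.0)

    tumor_center: Optional[Tuple[float, float, float]] = None  # default: right frontal
    cavity_radius: float = 8.0
    core_radius: float = 15.0       # enhancing core incl. cavity
    flair_radius: float = 25.0      # T2/FLAIR abnormality
    sigma_inf: float = 12.0         # infiltration decay length
    amplitude: float = 2.0          # peak fold-elevation at the core boundary
    baseline: float = 0.6           # NAWM Cho/NAA ratio
    noise_cv: float = 0.10          # multiplicative lognormal CV
    wm_inner: float = 0.30          # WM shell in normalized ellipsoid radius
    wm_outer: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.cavity_radius < self.core_radius < self.flair_radius):
            raise ValueError("radii must satisfy cavity < core < FLAIR, all > 0")
        if self.sigma_inf <= 0 or self.amplitude <= 0 or self.baseline <= 0:
            raise ValueError("sigma_inf, amplitude and baseline must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def clinical_grid(self) -> VolumeGrid:
        return VolumeGrid(self.clinical_shape, self.clinical_spacing, self.origin)

    @property
    def smri_grid(self) -> VolumeGrid:
        """Coarse grid covering the same world box, centers inside it."""
        extent = [(n - 1) * s for n, s in zip(self.clinical_shape, self.clinical_spacing)]
        shape = tuple(int(math.floor(e / s)) + 1 for e, s in zip(extent, self.smri_spacing))
        return VolumeGrid(shape, self.smri_spacing, self.origin)

    def resolved_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        grid = self.clinical_grid
        lo, hi = grid.world_bounds()
        bc = np.asarray(self.brain_center if self.brain_center is not None
                        else (lo + hi) / 2.0, dtype=float)
        if self.tumor_center is not None:
            tc = np.asarray(self.tumor_center, dtype=float)
        else:
            # right hemisphere (+x), anterior, mid-depth
            tc = bc + np.array([0.5 * self.brain_semiaxes[0],
                                0.1 * self.brain_semiaxes[1], 0.0])
        return bc, tc


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic patient."""

    params: PhantomParams
    brain: Mask
    hemispheres: np.ndarray          # 1 = left (-x), 2 = right (+x), 0 = outside
    tumor_side: int
    wm_prob: ScalarMap
    gtv1: Mask                       # FLAIR abnormality
    gtv2: Mask                       # enhancement + cavity
    infiltration: ScalarMap          # continuous f(x) on the clinical grid
    cho: ScalarMap                   # coarse sMRI grid
    naa: ScalarMap
    cho_naa: ScalarMap
    recurrence: Optional[Mask] = None
    doses: Dict[str, ScalarMap] = field(default_factory=dict)

    def analytic_fold_region(self, level: float) -> Mask:
        """Clinical-grid voxelization of the analytic region {1 + f >= level}."""
        r = analytic_threshold_radius(self.params, level)
        if r is None:
            return Mask(self.brain.grid, np.zeros(self.brain.grid.shape, bool),
                        f"analytic_fold{level:g}")
        _, tc = self.params.resolved_centers()
        gx, gy, gz = self.brain.grid.voxel_centers()
        d2 = (gx - tc[0]) ** 2 + (gy - tc[1]) ** 2 + (gz - tc[2]) ** 2
        return Mask(self.brain.grid, (d2 <= r * r) & self.brain.data,
                    f"analytic_fold{level:g}")


def analytic_threshold_radius(p: PhantomParams, level: float) -> Optional[float]:
    """World-mm radius of the noiseless region where Cho/NAA fold >= level.

    The fold field is 1 + f with f = A exp(-d^2/sigma^2) outside the core,
    so {fold >= L} is the sphere of radius core + sigma*sqrt(ln(A/(L-1)))
    for 1 < L <= 1 + A, the core itself at L = 1 + A, and empty above.
    """
    excess = level - 1.0
    if excess > p.amplitude:
        return None
    if excess <= 0:
        return math.inf
    return p.core_radius + p.sigma_inf * math.sqrt(max(0.0, math.log(p.amplitude / excess)))


def _sphere(grid_coords, center, radius):
    gx, gy, gz = grid_coords
    return ((gx - center[0]) ** 2 + (gy - center[1]) ** 2
            + (gz - center[2]) ** 2) <= radius * radius


def generate_phantom(p: PhantomParams) -> PhantomTruth:
    """Generate anatomy, ground-truth infiltration and coarse metabolite maps.

    Deterministic for a fixed ``p.seed``. Raises ``ValueError`` if the
    tumor center lies outside the brain ellipsoid.
    """
    grid = p.clinical_grid
    bc, tc = p.resolved_centers()
    ax = np.asarray(p.brain_semiaxes, dtype=float)

    if np.sum(((tc - bc) / ax) ** 2) > 1.0:
        raise ValueError(f"tumor center {tuple(tc)} lies outside the brain ellipsoid")

    gx, gy, gz = grid.voxel_centers()
    rho2 = (((gx - bc[0]) / ax[0]) ** 2 + ((gy - bc[1]) / ax[1]) ** 2
            + ((gz - bc[2]) / ax[2]) ** 2)
    brain_arr = rho2 <= 1.0
    brain = Mask(grid, brain_arr, "brain")

    hemis = np.zeros(grid.shape, dtype=np.int8)
    hemis[brain_arr & (gx < bc[0])] = 1
    hemis[brain_arr & (gx >= bc[0])] = 2
    tumor_side = 2 if tc[0] >= bc[0] else 1

    rho = np.sqrt(rho2)
    wm = np.where(brain_arr & (rho >= p.wm_inner) & (rho <= p.wm_outer), 0.95, 0.05)
    wm_prob = ScalarMap(grid, np.where(brain_arr, wm, 0.0), "arbitrary-signal",
                        valid=np.ones(grid.shape, bool))

    gtv2 = Mask(grid, _sphere((gx, gy, gz), tc, p.core_radius) & brain_arr, "GTV2")
    gtv1_arr = _sphere((gx, gy, gz), tc, p.flair_radius) & brain_arr
    gtv1 = Mask(grid, gtv1_arr | gtv2.data, "GTV1")

    d_out = np.sqrt((gx - tc[0]) ** 2 + (gy - tc[1]) ** 2 + (gz - tc[2]) ** 2)
    d_out = np.maximum(0.0, d_out - p.core_radius)
    f_clin = np.where(brain_arr, p.amplitude * np.exp(-(d_out / p.sigma_inf) ** 2), 0.0)
    infiltration = ScalarMap(grid, f_clin, "fold-normal", valid=brain_arr.copy())

    cho, naa, cho_naa = _sample_metabolites(p, bc, tc, ax)

    return PhantomTruth(
        params=p, brain=brain, hemispheres=hemis, tumor_side=tumor_side,
        wm_prob=wm_prob, gtv1=gtv1, gtv2=gtv2, infiltration=infiltration,
        cho=cho, naa=naa, cho_naa=cho_naa,
    )


def _sample_metabolites(p: PhantomParams, bc, tc, ax):
    """Evaluate the analytic fields at the coarse voxel centers."""
    sg = p.smri_grid
    gx, gy, gz = sg.voxel_centers()
    rho2 = (((gx - bc[0]) / ax[0]) ** 2 + ((gy - bc[1]) / ax[1]) ** 2
            + ((gz - bc[2]) / ax[2]) ** 2)
    support = rho2 <= 1.0

    d = np.sqrt((gx - tc[0]) ** 2 + (gy - tc[1]) ** 2 + (gz - tc[2]) ** 2)
    d = np.maximum(0.0, d - p.core_radius)
    f = p.amplitude * np.exp(-(d / p.sigma_inf) ** 2)

    rng = np.random.default_rng(p.seed)
    if p.noise_cv > 0:
        s2 = math.log(1.0 + p.noise_cv ** 2)
        g = rng.normal(-0.5 * s2, math.sqrt(s2), size=sg.shape)
    else:
        g = np.zeros(sg.shape)

    naa0 = 1.0
    cho0 = p.baseline * naa0
    lift = np.sqrt(1.0 + f)
    cho_vals = np.where(support, cho0 * lift * np.exp(0.5 * g), 0.0)
    naa_vals = np.where(support, naa0 / lift * np.exp(-0.5 * g), 0.0)
    ratio = np.where(support, p.baseline * (1.0 + f) * np.exp(g), 0.0)

    cho = ScalarMap(sg, cho_vals, "arbitrary-signal", valid=support.copy())
    naa = ScalarMap(sg, naa_vals, "arbitrary-signal", valid=support.copy())
    cho_naa = ScalarMap(sg, ratio, "arbitrary-signal", valid=support.copy())
    return cho, naa, cho_naa


def generate_dose(targets: Sequence[Tuple[Mask, float]], grid: VolumeGrid,
                  penumbra_mm: float = 5.0) -> ScalarMap:
    """Parametric conformal dose surrogate.

    dose(x) = max over targets of Rx * s(d(x)), with d the anisotropic
    Euclidean distance (mm) outside the target and the falloff

        s(d) = 1                      for d <= 0
        s(d) = 2 / (1 + exp(d / penumbra_mm))   for d > 0

    so every target voxel receives at least its prescription and dose is
    monotonically non-increasing with distance from each target.
    """
    if not targets:
        raise ValueError("generate_dose requires at least one target")
    if penumbra_mm <= 0:
        raise ValueError("penumbra_mm must be positive")
    dose = np.zeros(grid.shape)
    for mask, rx in targets:
        if not mask.grid.close_to(grid):
            raise ValueError(f"target {mask.label!r} is not on the dose grid")
        if mask.is_empty:
            continue
        d = ndimage.distance_transform_edt(~mask.data, sampling=grid.spacing)
        s = np.where(d <= 0, 1.0, 2.0 / (1.0 + np.exp(np.minimum(d, 50 * penumbra_mm)
                                                      / penumbra_mm)))
        np.maximum(dose, rx * s, out=dose)
    return ScalarMap(grid, dose, "Gy", valid=np.ones(grid.shape, bool))


def dose_falloff(d_mm: float, penumbra_mm: float = 5.0) -> float:
    """The documented penumbra profile s(d) used by :func:`generate_dose`."""
    if d_mm <= 0:
        return 1.0
    return 2.0 / (1.0 + math.exp(d_mm / penumbra_mm))


def generate_recurrence(truth: PhantomTruth, volume_cm3: float = 10.0,
                        mixing: float = 1.0, seed: int = 0) -> Mask:
    """Simulate a recurrent-tumor mask.

    A seed voxel is drawn with probability proportional to
    ``mixing * f(x) * [brain minus GTV2] + (1 - mixing) * [brain]`` —
    i.e. preferentially where pre-treatment Cho/NAA was elevated outside
    the enhancing core at full mixing, uniformly over the brain at the
    null setting — then grown as the nearest-voxel (world-mm) ball
    clipped to the brain until the requested volume is reached.
    """
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must be in [0, 1]")
    grid = truth.brain.grid
    if volume_cm3 <= 0:
        return Mask(grid, np.zeros(grid.shape, bool), "recurrence")

    brain = truth.brain.data
    f = truth.infiltration.values
    w = mixing * np.where(brain & ~truth.gtv2.data, f, 0.0) \
        + (1.0 - mixing) * brain.astype(float)
    total = w.sum()
    if total <= 0:
        w = brain.astype(float)
        total = w.sum()

    rng = np.random.default_rng(seed)
    flat_idx = rng.choice(w.size, p=(w / total).ravel())
    seed_ijk = np.unravel_index(flat_idx, grid.shape)
    seed_xyz = grid.index_to_world(np.asarray(seed_ijk))

    gx, gy, gz = grid.voxel_centers()
    dist2 = ((gx - seed_xyz[0]) ** 2 + (gy - seed_xyz[1]) ** 2
             + (gz - seed_xyz[2]) ** 2)
    n_needed = int(round(volume_cm3 / grid.voxel_volume_cm3))
    cand = np.flatnonzero(brain.ravel())
    order = cand[np.argsort(dist2.ravel()[cand], kind="stable")]
    chosen = order[:min(n_needed, order.size)]
    rec = np.zeros(grid.shape, dtype=bool)
    rec.ravel()[chosen] = True
    return Mask(grid, rec, "recurrence")
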