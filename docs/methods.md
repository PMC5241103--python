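# Methods

## Coordinate and grid conventions

All volumes live on regular, axis-aligned, right-handed 3D grids.
Voxel indices are 0-based; world coordinates are millimetres at voxel
centers; a grid is (shape, spacing, origin) with the origin at the
center of voxel (0,0,0). NIfTI volumes with oblique affines are
rejected after canonical reorientation rather than silently resampled —
every orientation bug in multi-grid pipelines traces back to implicit
reorientation. Scalar maps carry an explicit boolean validity mask
(companion array, not sentinel values), so reference-region statistics
exclude invalid voxels instead of diluting them; on disk, invalid
voxels are stored as NaN and validity is reconstructed as `isfinite`.

Two grids matter: a fine "clinical" grid (default 1.5 mm isotropic,
120³, i.e. a 180 mm box — a reduced profile chosen so full pipelines
run in seconds; ~1 mm full-size grids are a parameter change) and a
coarse "spectroscopic" grid of 4.4 × 4.4 × 5.6 mm voxels covering the
same world box. Metabolite maps are *generated* on the coarse grid and
must cross to the clinical grid through trilinear interpolation,
exercising the partial-volume behaviour that real spectroscopic data
undergo.

## Contour rasterization

Structure sets are per-slice closed polygons with world-mm vertices
(JSON dialect; DICOM-RT is transport, not method). Rasterization uses
the voxel-center even–odd rule: a voxel belongs iff its center lies
inside an odd number of polygons on that slice, so nested contours
subtract as holes. This matches how planning systems binarize and is
exactly testable by brute-force point-in-polygon. The inverse
(`extract_contours`) traces 0.5-level iso-contours of the binary slice,
which lie halfway between member and non-member centers; round-trip
Dice ≥ 0.99 holds for features spanning ≥ 3 voxels (below that,
single-voxel spurs can be lost, a documented limitation).

## Resampling

Trilinear interpolation in world coordinates between voxel centers.
The interpolant is exact on affine fields and bounded by the stencil's
extremes. Destination voxels outside the per-axis voxel-center hull,
or whose stencil touches an invalid source voxel (checked by
interpolating the validity indicator and requiring weight 1), are
flagged invalid. Disjoint grids produce an all-invalid output with a
warning rather than an error, because a cohort run must survive one bad
registration.

## Fold normalization

The Cho/NAA ratio is computed voxelwise where both inputs are valid and
NAA exceeds a small floor (default 1e-6; voxels at the floor are
invalidated, never clipped). The reference region is contralateral
normal-appearing white matter: {WM probability ≥ 0.9} in the hemisphere
opposite the tumor, minus the FLAIR abnormality dilated by a 10 mm
safety margin, and must exceed 10 cm³ or normalization is refused. The
probability cutoff, margin and minimum size are package defaults (no
published values exist for them); all three are arguments. The fold
map is the ratio divided by its mean over valid NAWM — mean exactly 1.0
over the reference by construction, idempotent, and invariant to global
rescaling of the input. Normalizing the ratio (default) and
normalizing Cho and NAA separately before ratioing differ whenever Cho
and NAA covary within NAWM; both are implemented (`fold_cho_naa`,
`mode=`). Threshold segmentations use the closed comparison
(fold ≥ level), the conservative choice that yields the larger target,
and are clipped to brain and validity; by default the fold map is
upsampled first and thresholded second (threshold-then-upsample is
available by composing the operations the other way on the coarse map).

## Margin expansion and target chains

Margins are metric: the expanded mask is every voxel whose center lies
within the margin of a member voxel center, computed by an exact
Euclidean distance transform with anisotropic sampling — at 5.6 mm
slice spacing an isotropic structuring element is wrong by up to a
slice. This center-distance semantics is verified exactly against an
all-pairs distance oracle. Two consequences are documented rather than
hidden: a voxelized sphere expanded by m mm undershoots the analytic
(r+m) ball by ~2–3% at 1 mm spacing, and *sequential* margining (GTV →
CTV → PTV) compounds the undershoot (a point GTV's 5+3 mm chain lands
~6% under the analytic 8 mm ball) because the second expansion measures
from the first expansion's voxel centers.

CTV expansions are clipped to the brain external contour (microscopic
spread does not cross bone); PTV expansions are not clipped (setup
uncertainty is a property of positioning, not anatomy). The
sMRI-modified chain is pure union: sMRI_CTV2 = CTV2 ∪ segmentation,
sMRI_CTV1 = sMRI_CTV2 ∪ CTV1, each plus the 3 mm PTV margin — so a
conventionally targeted voxel can never be dropped, and sMRI_CTV2
volume is non-increasing in the fold threshold.

Defaults mirror standard glioblastoma practice: 7/5 mm CTV margins,
3 mm PTV margins, 51 Gy (or 54) to PTV1 and 60 Gy to PTV2 in 30
fractions, organ-at-risk ceilings of 54 Gy soft (optic structures,
brainstem, with ≤10% of brainstem above it) and 60 Gy hard point max
for brainstem, coverage goal 95% of target at prescription with a 90%
relaxed floor for PTV2 near the brainstem.

## Dose surrogate

Inverse planning is replaced by a parametric conformal model:
`dose(x) = max_t Rx_t · s(d_t(x))` with `d_t` the anisotropic Euclidean
distance outside target `t`, and the penumbra profile `s(d) = 1` for
`d ≤ 0`, `s(d) = 2/(1 + exp(d/p))` for `d > 0` (p = 5 mm default).
The profile is continuous at the target surface, strictly decreasing,
and delivers exactly the prescription throughout each target, so
generated plans cover 100% of every target at prescription by
construction — the coverage *goal* is a property of the surrogate, and
coverage tests on it check the metric plumbing, not an optimizer. The
max rule makes nested boost volumes well-defined. What the surrogate
does not model: beam geometry, inhomogeneity, optimizer trade-offs
between coverage and organ sparing — so brainstem-dose findings on
phantoms characterize geometry (distance from target to organ), not
achievable plans.

## Synthetic phantom

One phantom is: an ellipsoidal brain (semi-axes 70/80/65 mm) split into
hemispheres at the midsagittal plane; a deep white-matter shell
(probability 0.95 for normalized ellipsoidal radius in [0.30, 0.85],
0.05 elsewhere); nested spherical tumor compartments — cavity (8 mm) ⊂
enhancing core (15 mm, = GTV2) ⊂ FLAIR abnormality (25 mm, = GTV1) —
and a continuous infiltration field `f(x) = A·exp(−d(x)²/σ²)` where
`d` is distance outside the core, `A = 2` (so the ratio peaks at 3×
baseline) and `σ = 12 mm`. The Cho/NAA ratio is
`baseline·(1+f)·exp(g)` with `g ~ N(−s²/2, s²)`, `s² = ln(1+CV²)`,
CV = 0.10 by default — multiplicative lognormal noise with unit mean,
appropriate for positive, heteroscedastic ratio data; no published
noise model for spectroscopic ratio maps exists, so this noise model is
synthetic and labelled as such. Cho and NAA are `cho0·√(1+f)·e^{g/2}`
and `naa0·e^{−g/2}/√(1+f)` — choline elevated and NAA suppressed toward
the core — so their quotient reproduces the ratio field exactly. The
baseline ratio 0.6 places the 1.5–2.0-fold thresholds at absolute
ratios 0.9–1.2, the range reported as pathological. Everything is
deterministic under a fixed seed.

Because the field is closed-form, ground truth is analytic: the
noiseless region {fold ≥ L} is the sphere of radius
`core + σ·√ln(A/(L−1))`. The recovery test (noiseless phantom, coarse
sampling → trilinear upsampling → threshold) achieves Dice ≥ 0.95
against this region, with voxelization and interpolation the only error
sources.

Recurrence is a nearest-voxel ball grown to a requested volume
(default 10 cm³) around a seed voxel drawn with probability
proportional to `mixing · f(x)` outside GTV2 plus `(1 − mixing)`
uniform over brain — at mixing = 1 recurrence arises preferentially
where pre-treatment Cho/NAA was elevated; at mixing = 0 the null,
uniform model. A small cylindrical midline "brainstem" surrogate
provides an organ-at-risk for dose constraints.

What the phantom does **not** emulate: real lesion shapes (spheres, not
infiltrative fingers), susceptibility and lipid artifacts, spatially
correlated noise, registration error, or inter-rater contour
variability. Passing tests therefore demonstrate correctness of the
*computational* chain — geometry, normalization, construction, metrics,
statistics — not clinical performance on patient data; cohort-level
numbers from phantoms agree with patient studies directionally (sMRI
targets larger, spatially distinct, better recurrence coverage), not in
magnitude.

## Statistics

Paired one-sided t, one-sample one-sided t against a fixed mean
(Dice vs 1.0), and one-way ANOVA are computed from the textbook
formulas; tail probabilities use the closed-form regularized incomplete
beta for the t and F distributions and are cross-checked against an
independent distribution implementation to 1e-9. Degenerate inputs
(n < 2, zero variance) raise with a message naming the degeneracy
instead of returning p-values — notably, ANOVA on noiseless-surrogate
coverage (all plans at exactly 100%) is degenerate and is skipped with
a logged warning in cohort runs. Test direction is an explicit
argument, never inferred from the data. No multiple-testing correction
is applied (none is applied in the practice this mirrors); the result
metadata says so.

## Problem sizes and numerical choices

The cohort pipeline and acceptance script run at the default reduced
phantom (120³ at 1.5 mm, 7 patients); unit and property tests use a
smaller 72³ at 2.0 mm profile where the property under test is
scale-free (oracle equivalence sweeps use random grids up to 20³, where
all-pairs distance oracles are exact and fast). Distance-transform
comparisons use a +1e-9 tolerance on the margin to absorb float
rounding at exact-equality radii; slice coplanarity of contours is
checked to 1e-3 of the slice spacing; both-empty Dice is defined as 1.0
(perfect-agreement convention, logged). Per-patient seeds are spawned
from the cohort seed via `SeedSequence([seed, i])` reduced below 2³¹,
making cohorts reproducible patient-by-patient.

## Known limitations

- Sequential-margin undershoot (above) is inherent to center-distance
  voxel semantics; sub-voxel (surface-distance) margining would trade
  oracle exactness for geometric accuracy.
- `extract_contours` loses single-voxel features.
- The recurrence model grows one connected ball; multifocal recurrence
  is out of scope.
- GTVs are inputs (or phantom spheres); no automatic tumor
  segmentation.
- Registration between spectroscopic and clinical grids is assumed
  perfect (inputs co-registered by construction).
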