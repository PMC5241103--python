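# smrirt

Spectroscopic-MRI guided radiotherapy target planning for glioblastoma,
as a reusable, testable Python pipeline.

Glioblastoma infiltrates well beyond what contrast-enhanced T1 and
T2/FLAIR MRI show, so conventional radiotherapy targets — gross tumor
volumes (GTV) expanded by fixed metric margins into clinical (CTV) and
planning (PTV) target volumes — can miss metabolically active disease.
Whole-brain spectroscopic MRI maps the choline to N-acetylaspartate
ratio (Cho/NAA), a marker of proliferative, non-neuronal tissue. This
package implements the full analysis chain that quantifies how Cho/NAA
abnormality volumes modify RT planning:

1. **Metabolite standardization.** Cho/NAA ratio maps on the coarse
   spectroscopic grid (4.4 × 4.4 × 5.6 mm voxels) are upsampled into the
   ~1 mm clinical grid by trilinear interpolation and divided by the
   mean ratio in contralateral normal-appearing white matter (NAWM),
   yielding *fold-normal* maps: `fold(x) = (Cho/NAA)(x) / mean_NAWM(Cho/NAA)`.
2. **Threshold segmentation.** Metabolic abnormality volumes at 1.5-,
   1.75- and 2.0-fold elevation.
3. **Target construction.** Conventional chains (CTV1 = GTV1 + 7 mm,
   CTV2 = GTV2 + 5 mm clipped to brain; PTV = CTV + 3 mm) and
   sMRI-modified chains (`sMRI_CTV2 = CTV2 ∪ segmentation`,
   `sMRI_CTV1 = sMRI_CTV2 ∪ CTV1`, + 3 mm PTV margins), with margins
   computed as exact anisotropic Euclidean distances.
4. **Metrics.** Dice overlap, volume increase, abnormality escaping the
   prescription isodose regions (51/54 and 60 Gy), target coverage,
   brainstem point-max dose, and recurrence coverage.
5. **Statistics.** One-sided paired t tests, one-sample t against 1.0
   (for Dice), and one-way ANOVA, from closed forms.
6. **Synthetic phantoms.** Since patient images cannot ship with the
   code, a phantom generator produces complete synthetic patients with
   closed-form ground truth — tumor-driven Cho elevation and NAA
   suppression with a Gaussian infiltration gradient
   `f(x) = A·exp(−d(x)²/σ²)` beyond the enhancing core, conformal dose
   surrogates, and recurrence masks biased toward pre-treatment
   metabolic abnormality — so every stage is testable end to end.

## Worked example

```python
from smrirt import (PhantomParams, generate_phantom, ratio_map,
                    resample_trilinear, segment_nawm, normalize_fold,
                    threshold_segmentation, build_conventional, build_smri,
                    dice, percent_increase)

truth = generate_phantom(PhantomParams(seed=7))
nawm  = segment_nawm(truth.wm_prob, truth.hemispheres, truth.tumor_side,
                     [truth.gtv1])
fold  = normalize_fold(resample_trilinear(ratio_map(truth.cho, truth.naa),
                                          truth.brain.grid), nawm)
conv  = build_conventional(truth.gtv1, truth.gtv2, truth.brain)
for level in (1.5, 1.75, 2.0):
    seg = threshold_segmentation(fold, level, truth.brain)
    pv  = build_smri(conv, seg)
    print(level, round(pv["sMRI_CTV2"].volume_cm3, 1),
          round(percent_increase(conv["CTV2"], pv["sMRI_CTV2"]), 1),
          round(dice(conv["CTV2"], seg), 3))
```

prints

```
1.5  104.5  226.8  0.469
1.75  81.6  155.2  0.563
2.0   64.8  102.6  0.661
```

i.e. on this phantom the NAWM-normalized Cho/NAA map thresholded at
1.5-fold delineates 104.5 cm³ of abnormality; merging it into the 32.0
cm³ conventional CTV2 grows the boost target by 226.8%, and the Dice of
0.469 shows the metabolic volume and the anatomical margin target
substantially different tissue — the motivation for sMRI-guided
planning. Higher thresholds give smaller, nested targets. The scripts
in `examples/` walk through each capability (phantom generation, fold
normalization, target chains, dose metrics, cohort statistics) and
print annotated output; a thin CLI (`smrirt phantom|metabolite|
plan-volumes|evaluate|stats|run-cohort`) wraps the same functions for
shell use.

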