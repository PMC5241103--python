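"""Generate a synthetic glioblastoma patient and inspect its ground truth.

The phantom carries everything downstream stages need: brain anatomy,
nested tumor compartments (cavity < enhancing core < FLAIR abnormality),
a continuous infiltration field, and Cho/NAA metabolite maps sampled on
the coarse spectroscopic grid with multiplicative noise.
"""

from smrirt import PhantomParams, generate_phantom

params = PhantomParams(seed=7)  # defaults: 120^3 at 1.5 mm, 10% noise CV
truth = generate_phantom(params)

print(f"clinical grid : {truth.brain.grid.shape} at "
      f"{truth.brain.grid.spacing} mm")
print(f"sMRI grid     : {truth.cho.grid.shape} at {truth.cho.grid.spacing} mm")
print(f"brain volume  : {truth.brain.volume_cm3:8.1f} cm3")
print(f"GTV1 (FLAIR)  : {truth.gtv1.volume_cm3:8.1f} cm3")
print(f"GTV2 (core)   : {truth.gtv2.volume_cm3:8.1f} cm3")
ratio = truth.cho_naa
print(f"Cho/NAA range : {ratio.values[ratio.valid].min():.2f} - "
      f"{ratio.values[ratio.valid].max():.2f} (baseline "
      f"{params.baseline}, so max ~= {(1 + params.amplitude)} x baseline "
      f"plus noise)")
# GTV2 < GTV1 < brain: the enhancing core sits inside the FLAIR
# abnormality; the Cho/NAA ratio peaks at ~3x white-matter baseline at
# the core and decays with the infiltration gradient beyond it.
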