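"""Generate a synthetic SD-OCT volume and inspect its ground truth.

The phantom stacks ten retinal layers over a foveal pit, renders a two-way
Beer-Lambert backscatter signal with multiplicative speckle, and records the
exact surfaces and attenuation values used.
"""

import numpy as np

from octquant.phantom import PhantomSpec, generate_volume

spec = PhantomSpec(seed=7)
volume, truth = generate_volume(spec)

print(f"volume: {volume.shape} voxels at {volume.voxel_size} um, "
      f"{volume.intensity.dtype}, quality score {volume.quality_score:.1f}")
print(f"field of view: {volume.enface_extent_mm()[0]:.1f} x "
      f"{volume.enface_extent_mm()[1]:.1f} mm")
print()
print("layer   mu(mm^-1)  backscatter  mean thickness(um)")
for layer, mu in truth.mu_by_layer.items():
    b = truth.backscatter_by_layer[layer]
    t = truth.thickness_maps[layer].mean()
    print(f"{layer:6s}  {mu:8.2f}  {b:11.2f}  {t:14.1f}")

pit = truth.analysis_thickness("mRNFL")
cx, cy = int(truth.fovea_index[0]), int(truth.fovea_index[1])
print()
print(f"inner-layer thickness at the pit center: {pit[cx, cy]:.1f} um "
      f"(vs {pit[0, 0]:.1f} um at the scan corner) — the pit thins the "
      "RNFL/GCL/IPL toward zero, which is what fovea detection relies on")
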