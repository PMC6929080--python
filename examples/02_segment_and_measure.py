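"""Segment a phantom and quantify the cornea-lens clearance (vault).

Runs the full pipeline (denoise, rotate, enhance, trace, snake-refine) on a
noisy central phantom and prints the clearance at the corneal apex under
the three correspondence paradigms, plus the segmentation error against the
known ground truth.
"""

import numpy as np

from octlens import PhantomSpec, generate_phantom
from octlens.evaluate import curve_error
from octlens.pipeline import measure, segment_image

image, truth = generate_phantom(PhantomSpec(scenario="central", vault=40.0, seed=3))
result = segment_image(image)
print(f"classified as {result.layers.region_class} "
      f"(confidence {result.layers.confidence:.2f})")

for name, true_curve in truth.curves.items():
    _, err, _ = curve_error(getattr(result.layers, name), true_curve)
    print(f"  {name:10s} MAE vs truth: {err:.2f} px")

profile = measure(result.layers)
apex = profile.cols[len(profile.cols) // 2]
v, n, near = profile.at(apex)
print(f"clearance at apex column {apex}: vertical {v:.1f} px, "
      f"normal {n:.1f} px, nearest {near:.1f} px (true vault 40)")
print(f"median clearance across the scan: {np.nanmedian(profile.nearest):.1f} px")
# The three paradigms agree at the apex where the layers run horizontally;
# they separate on tilted flanks, where 'nearest' is the faithful reading.
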