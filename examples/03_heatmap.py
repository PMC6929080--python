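"""Render the red-to-green clearance heatmap for a lateral phantom.

Red marks where the lens comes closest to the cornea, green where the
clearance is largest. The PNG is written next to this script.
"""

from pathlib import Path

from octlens import PhantomSpec, generate_phantom
from octlens.io import save_image
from octlens.pipeline import measure, segment_image
from octlens.viz import render_heatmap

image, _ = generate_phantom(PhantomSpec(scenario="lateral", seed=5))
result = segment_image(image)
profile = measure(result.layers)
render = render_heatmap(image, result.layers, profile, paradigm="nearest")

out = Path(__file__).with_name("lateral_heatmap.png")
save_image(out, render.rgb)
print(f"clearance range [{render.vmin:.1f}, {render.vmax:.1f}] px -> {out.name}")
print("red = lens touching down on the tissue side, green = full vault")
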