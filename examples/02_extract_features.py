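"""Extract colour, vegetation-index and texture features from one plot.

Indices are computed on the ROI-mean colour (the plot-mean convention);
texture statistics come from gray-level co-occurrence matrices at the four
standard angles, aggregated by their directional mean and SD.
"""

import numpy as np

from canopy_yield import ROI, SceneParams, simulate_plot_image
from canopy_yield.color_features import summarize_color
from canopy_yield.texture_features import texture_vector

params = SceneParams()
tile, _ = simulate_plot_image(params, 6.0, np.random.default_rng(1),
                              defoliation_level=0.6)
roi = ROI(box=(0, 0, params.tile_size, params.tile_size))

summary, vis = summarize_color(tile, roi)
print(f"mean DN (R,G,B)  : ({summary.R:.1f}, {summary.G:.1f}, {summary.B:.1f})")
print(f"chromatic (r,g,b): ({summary.r:.4f}, {summary.g:.4f}, {summary.b:.4f})")
print(f"ExG              : {vis.ExG:+.4f}   (greenness; falls as leaves drop)")
print(f"NGRDI            : {vis.NGRDI:+.4f}")
print(f"CIVE             : {vis.CIVE:.4f}")

tex = texture_vector(tile, roi)
print(f"CON_MEAN         : {tex['CON_MEAN']:.3f}  (contrast over 4 angles)")
print(f"CON_SD           : {tex['CON_SD']:.3f}  (texture anisotropy)")
print(f"ASM_MEAN         : {tex['ASM_MEAN']:.4f} (uniformity)")
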