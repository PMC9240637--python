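"""Render a synthetic cotton plot tile and inspect its composition.

The scene mimics a pre-harvest cotton field seen from a low-altitude RGB
survey: plastic mulch-film strips over soil, green canopy thinned by
defoliant, and white open bolls whose count encodes the plot yield
(1 t/ha = 100 g/m2, divided by the single-boll weight, times the tile's
ground area).
"""

import numpy as np

from canopy_yield import SceneParams, boll_count, simulate_plot_image
from canopy_yield.synthetic import BOLL, CANOPY, FILM, SOIL

params = SceneParams()  # 256 px tiles at 0.3 cm/px -> 0.59 m2 of ground
yield_t_ha = 4.5

n_bolls = boll_count(yield_t_ha, params.boll_weight_g, params.tile_area_m2)
print(f"tile ground area     : {params.tile_area_m2:.4f} m2")
print(f"yield                : {yield_t_ha} t/ha = {yield_t_ha * 100:.0f} g/m2")
print(f"bolls drawn          : {n_bolls} (at {params.boll_weight_g} g/boll)")

tile, mask = simulate_plot_image(params, yield_t_ha,
                                 np.random.default_rng(0),
                                 defoliation_level=0.5)
for name, cls in [("soil", SOIL), ("film", FILM),
                  ("canopy", CANOPY), ("boll", BOLL)]:
    print(f"{name:6s} cover        : {100 * (mask == cls).mean():5.1f} %")

# The boll cover fraction is the yield signal the pipeline exploits; canopy
# cover is controlled by defoliation, independent of yield.
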