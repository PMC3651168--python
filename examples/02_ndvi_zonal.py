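"""NDVI from a two-band image and 100-m zonal summaries at points.

Builds the coarse 30-m red/NIR rendering of a habitat mosaic, computes
NDVI = (NIR - Red) / (NIR + Red), and summarizes it as mean and SD inside
a 100-m circle around three sample points — exactly the per-point
predictors used in the habitat regressions.
"""

import pandas as pd

from habtex import Raster, compute_ndvi, zonal_summary, zonal_table
from habtex.synthetic import TruthConfig, generate_habitat_map, \
    render_reflectance

habitat = generate_habitat_map((1200, 1200), 10.0, seed=4)
coarse = render_reflectance(habitat, "coarse", TruthConfig(), seed=5)
red = Raster(coarse.values[0], coarse.origin_x, coarse.origin_y,
             coarse.cell_size)
nir = Raster(coarse.values[1], coarse.origin_x, coarse.origin_y,
             coarse.cell_size)
ndvi = compute_ndvi(red, nir)
print(f"NDVI range: {ndvi.band(0)[ndvi.mask].min():.3f} .. "
      f"{ndvi.band(0)[ndvi.mask].max():.3f}")

points = pd.DataFrame({"id": ["a", "b", "c"],
                       "x": [300.0, 600.0, 900.0],
                       "y": [300.0, 600.0, 900.0]})
table = zonal_table(zonal_summary(ndvi, points, 100.0, "ndvi"))
print(table.to_string(index=False))
# 'n' counts the 30-m pixels whose centers fall inside each circle
# (37 for a center-aligned point); mean/sd are the per-point predictors.
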