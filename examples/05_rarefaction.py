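"""Species-accumulation (rarefaction) curve from survey incidences.

Builds a visit-level incidence matrix from simulated observations and
permutes the sample order 1000 times. A plateau means most of the
community was seen; the SD band shows ordering uncertainty.
"""

import numpy as np

from habtex import accumulation_curve

rng = np.random.default_rng(12)
# 18 survey events x 25 species; commoner species in the low columns
incidence = rng.random((18, 25)) < np.linspace(0.65, 0.04, 25)

curve = accumulation_curve(incidence, n_permutations=1000, seed=12,
                           habitat="savanna")
frame = curve.to_frame()
print(frame.iloc[[0, 2, 5, 9, 17]].to_string(index=False))
print(f"pooled richness: {int(curve.mean_richness[-1])} species "
      f"(curve endpoint; SD there is exactly 0)")
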