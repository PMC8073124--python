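"""Run one preprocessing combination through the full single-set pipeline.

Pipeline order: drop the water-vapor region, denoise, interpolate across
the CO₂ band, correct the baseline, trim CO₂ out, normalize.
"""

import numpy as np

import ftirgrid as fg
from ftirgrid.grid import MethodSpec, preprocess_set

study = fg.generate_study(seed=1)
triple = (
    MethodSpec("denoise", "SG", (("poly_degree", 2), ("frame", 15))),
    MethodSpec("baseline", "ALS", (("lambda", 1e6),)),
    MethodSpec("normalize", "CON"),
)
out = preprocess_set(study, triple)

idx = out.axis.nearest_index(1656.0)
print("combination:", "|".join(s.label() for s in triple))
print(f"variables: {study.n_variables} -> {out.n_variables} (CO2 and water-vapor regions removed)")
print(f"Amide I point after CON normalization: {out.absorbance[:, idx].mean():.3f} (should be 1)")
print(f"baseline-corrected minimum: {out.absorbance.min():.3f} AU")
# After ALS the slowly varying drift is gone; CON scales every spectrum
# so the Amide I band is exactly 1, making spectra comparable.
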