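"""Generate the synthetic 48-spectrum study and inspect its structure.

Creates five classes of prostate-cell-line-like spectra (14/7/7/10/10) on
a 1582-point axis over 900-3800 cm⁻¹, distorted with baseline drift,
Mie-type scatter fringes, multiplicative scaling, CO₂/water-vapor bands
and detector noise, then writes it to a TSV file.
"""

import numpy as np

import ftirgrid as fg

study = fg.generate_study(seed=1)
labels, counts = np.unique(study.labels, return_counts=True)

print(f"spectra matrix: {study.n_spectra} x {study.n_variables}")
print(f"axis: {study.axis.values[0]:.0f}..{study.axis.values[-1]:.0f} cm^-1")
print("class sizes:", {str(l): int(c) for l, c in zip(labels, counts)})
print(f"absorbance range: {study.absorbance.min():.3f}..{study.absorbance.max():.3f} AU")

fg.write_spectra(study, "study.tsv")
print("wrote study.tsv (one column per spectrum, header id|class)")
# The matrix mimics the measurement design the pipeline is benchmarked
# on: every preprocessing method downstream has a distortion to correct.
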