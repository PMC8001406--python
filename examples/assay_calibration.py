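"""Spectrophotometric assay arithmetic: DPPH inhibition and the
standard-curve conversion of an absorbance to mg equivalents per gram
of fresh leaf.
"""

import numpy as np

from bandpop.assays import fit_standard_curve, percent_inhibition, to_equivalents

print(f"DPPH inhibition for blank A=0.80, extract A=0.60: "
      f"{percent_inhibition(0.80, 0.60):.1f}%")

# gallic-acid calibration over 20-80 ug/mL
conc = np.array([20, 40, 60, 80], float)
absorb = 0.010 * conc + 0.015 + np.array([0.003, -0.002, 0.001, -0.001])
curve = fit_standard_curve(conc, absorb, analyte="gallic acid")
print(f"standard curve: A = {curve.slope:.4f} c + {curve.intercept:.4f} "
      f"(r2 = {curve.r2:.3f}, range {curve.valid_range} ug/mL)")

mg_per_g = to_equivalents(0.5, curve, dilution_factor=10,
                          extract_volume_ml=3.0, leaf_mass_g=0.5)
print(f"a reading of A = 0.5 at 10x dilution from 0.5 g leaf in 3 mL "
      f"extract = {mg_per_g:.2f} mg GAE/g fresh leaf")
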