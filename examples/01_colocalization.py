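"""Shift-resolved Pearson colocalization of two tagged proteins.

Simulates eight two-channel cells with half of the second channel's puncta
co-placed on the first channel's puncta (rho = 0.5), draws a segmented-line
profile through each cell, and averages the Pearson-vs-shift curves.
"""

import numpy as np

from aggrescope import coloc, syndata

spec = syndata.CellSpec(coloc_fraction=0.5)
images, roisets, truth = syndata.simulate_coloc_cells(8, spec, seed=11)

curves = []
for img, rs in zip(images, roisets):
    profile = coloc.extract_profile(img, rs.rois[0], "ch1", "ch2")
    shifts, r, _ = coloc.shift_correlation(profile, max_shift=10)
    curves.append((shifts, r))

curve = coloc.aggregate_curves(curves, min_cells=6)
mid = len(curve.shifts) // 2
print(f"planted colocalization fraction rho = {truth.params['rho']}")
print(f"mean Pearson r at zero shift: {curve.r[mid]:.3f} +/- {curve.se[mid]:.3f} "
      f"(n = {curve.n[mid]} cells)")
print(f"r at +5 px shift:             {curve.r[mid + 5]:.3f}")
print()
print("r(0) > 0 reports colocalization of the two channels; the fall-off")
print("away from zero shift reflects the spatial size of the co-occurring")
print("puncta, and partially colocalized channels sit between the r(0)")
print("values of independent (rho=0) and perfectly co-placed (rho=1) signal.")
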