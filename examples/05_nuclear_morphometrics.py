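"""Nuclear condensation measured as the FWHM of a 2-D Gaussian fit.

Simulates two groups of histone-tagged nuclei -- normal (sigma = 10 px) and
condensed (sigma = 6 px) -- fits each to an isotropic 2-D Gaussian, and
compares group FWHMs with Welch's t-test.
"""

from aggrescope import morpho, syndata

images, truth = syndata.simulate_nuclei(30, sigmas=[10.0, 6.0], seed=2)
fwhms = {0: [], 1: []}
for img, rec in zip(images, truth.records):
    fit = morpho.fit_nucleus_2d(img, "rfp")
    fwhms[rec["group"]].append(fit.fwhm)

out = morpho.compare_groups(fwhms[0], fwhms[1])
print(f"normal nuclei:    mean FWHM {out['mean_a']:.2f} px (n = {out['n_a']})")
print(f"condensed nuclei: mean FWHM {out['mean_b']:.2f} px (n = {out['n_b']})")
print(f"Welch t = {out['t']:.2f}, p = {out['p']:.2e}")
print()
print("FWHM = 2*sqrt(2 ln 2)*sigma, so planted widths of 10 and 6 px give")
print("23.5 and 14.1 px.  A significantly smaller FWHM in cells exposed to")
print("the poison is the quantitative signature of nuclear condensation,")
print("an apoptosis-like death marker.")
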