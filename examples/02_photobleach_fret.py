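"""Acceptor-photobleaching FRET between co-assembled poison and antidote.

Simulates 50 cells whose donor is quenched by a planted 40% transfer
efficiency, bleaches the acceptor at 95% efficiency, and summarizes the
recovered efficiency across cells.
"""

from aggrescope import fret, syndata

pairs, roisets, truth = syndata.simulate_bleach_pairs(
    50, e_true=0.40, bleach_efficiency=0.95, seed=11
)
measurements = [
    fret.measure_bleach_pair(pre, post, rs.rois[0], cell_id=f"cell{i}")
    for i, ((pre, post), rs) in enumerate(zip(pairs, roisets))
]
summary = fret.summarize_fret(measurements)

print(f"planted FRET efficiency:    {100 * truth.params['e_true']:.1f}%")
print(f"recovered mean efficiency:  {summary.mean_percent:.2f}% "
      f"+/- {100 * summary.se:.2f}% (n = {summary.n})")
print(f"cells excluded:             {len(summary.exclusions)}")
print()
print("Bleaching the acceptor de-quenches the donor; the fractional donor")
print("increase (D_post - D_pre)/D_post estimates the transfer efficiency.")
print("The recovered mean sits just below the planted value because a 95%")
print("bleach leaves a residual 5% of the acceptor still quenching.")
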