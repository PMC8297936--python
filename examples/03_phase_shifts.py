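"""Quantify a planted phase delay between populations.

The cave population's oscillations are delayed by 2 h. Phase shifts are
minimal signed clock distances between peak times of genes rhythmic
(p < 0.05) in both populations, tested with the Wilcoxon signed-rank
statistic against a zero median.
"""

import cavechrono as cc
from cavechrono import simulate

truth = simulate.make_gene_truth(
    n_genes=150, populations=("Surface", "Cave"), rhythmic_fraction=1.0,
    amplitude=1.0, dispersion=0.05, phase_shift={"Cave": 2.0}, seed=3,
)
matrix, _ = simulate.simulate_expression(truth, seed=3)
table = cc.rhythm_table(matrix)
per_pop = {p: table[table["population"] == p] for p in ("Surface", "Cave")}

records = cc.phase_shift_records(per_pop["Surface"], per_pop["Cave"], p_threshold=0.05)
mean, median, p = cc.phase_shift_test(records)
print(f"jointly rhythmic genes: {len(records)}")
print(f"mean shift   : {mean:+.2f} h  (planted +2.00 h)")
print(f"median shift : {median:+.2f} h")
print(f"signed-rank p: {p:.3g}")
# Positive shifts mean the cave peaks later; the mean recovers the planted
# delay to within the 4-h lag-grid resolution of the phase estimate.

hist = cc.phase_histogram(per_pop["Surface"], bin_width=4)
print(hist.to_string(index=False))
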