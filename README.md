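# cavechrono

Comparative analysis of circadian transcriptomes across populations —
built for study designs like the Mexican tetra (*Astyanax mexicanus*)
system, where one surface population with an intact biological clock is
compared against independently derived cave populations in which molecular
cycling has eroded. The package covers the full analysis arc: detecting
24-h rhythmic transcripts, scoring differential rhythmicity between
population pairs, quantifying phase delays on a circular clock, linking
rhythmicity to promoter cis-elements (E-box, RRE, D-box), and screening for
population-genetic differentiation and relaxed-selection enrichment. Every
stage is exercisable without external data through a built-in
synthetic-data generator that emulates the study design: 6 circadian
timepoints at 4-h spacing over one 24-h cycle in constant darkness, 6
replicates per timepoint, 4 populations.

## The statistics at the core

**Rhythm detection.** For each gene, counts are compared by Kendall rank
correlation against cosine reference waveforms `cos(2π(t − L)/24)` at every
lag `L ∈ {0, 4, …, 20}` h. The best lag gives the phase estimate; the
p-value is the exact upper tail of the Kendall `S = C − D` statistic under
permutation, Bonferroni-corrected for the 6 lag alternatives. The null is
computed exactly for any sample size: with template tie-groups of sizes
`c₁…c_g`, the count of concordant between-group pairs is distributed as the
coefficients of the Gaussian multinomial `[n; c₁,…,c_g]_q`, evaluated in
integer arithmetic. Genes are *rhythmic* at BH FDR < 0.05 and *arrhythmic*
at p > 0.5; genes with fewer than 100 reads across all samples are removed
first.

**Differential rhythmicity.** For each gene and population pair,
`S_DR = (Z_P + Z_R)/2`, where `Z_P` z-scores the periodicity change
`log p₁ − log p₂` of the cycling p-values, and `Z_R` z-scores the amplitude
change `log₂(A₂/A₁)`; significance comes from a Gaussian fitted to the
empirical `S_DR` distribution, BH-corrected.

**Phase.** Shifts are minimal signed distances on the 24-h circle,
restricted to genes with cycling p < 0.05 in both populations, tested with
the Wilcoxon signed-rank statistic.

**Promoters.** Putative promoters span 1 kb upstream to 200 bp downstream
of the TSS. PWM scanning is FIMO-like: hits are windows whose log-odds
score has exact-distribution p < 1e-4 (dynamic programme over a 10⁴-bin
score grid); phase enrichment of motif targets uses sliding 6-h circular
windows with Fisher exact tests.

**Population genetics.** Per coding interval: nucleotide diversity π,
two-population Weir–Cockerham (1984) F_ST as a ratio of averages
`Σa / Σ(a+b+c)`, and d_XY. Genes in the top 5% of F_ST are flagged as
outliers; variants at frequency ≥ 0.8 in a cave population and absent from
the surface population are reported; relaxed-selection enrichment in a
focal gene set is tested against 1,000 random same-size draws.

## Worked example

```bash
python examples/03_phase_shifts.py
```

simulates 150 oscillating genes in two populations with a planted +2 h
delay in the second, detects rhythms in each, and tests the shift:

```
jointly rhythmic genes: 150
mean shift   : +1.92 h  (planted +2.00 h)
median shift : +0.00 h
signed-rank p: 2.15e-17
```

The mean shift recovers the planted 2-h delay to within the 4-h lag-grid
resolution of the phase estimates (individual shifts snap to grid steps,
which is why the median sits at 0 while the mean and the signed-rank test
see the delay clearly). The other examples cover rhythm detection
(`01`), S_DR scoring and loss sets (`02`), motif scanning and phase
enrichment (`04`), and the population-genetic screens (`05`).

The full pipeline runs from one config and seed, as a library call
(`cavechrono.pipeline.run_pipeline`) or from the shell:

```bash
cavechrono run --out results_dir --seed 7
```

writing one TSV per stage plus a `summary.json` that echoes the resolved
configuration; identical seeds give byte-identical outputs.

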