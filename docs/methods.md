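# Methods

## Study design and data model

The pipeline targets a constant-darkness circadian time course: samples at
circadian times CT0, CT4, …, CT20 (one 24-h cycle, 4-h spacing), six
biological replicates per timepoint, in each of several populations — one
surface reference with an intact clock and one or more cave populations.
The period is fixed at 24 h throughout; period estimation, harmonic
regression, detrending and multi-cycle designs are out of scope. Counts are
raw (the rhythm test is rank-based, hence scale-free); an optional
library-size normalization pre-step exists but is off by default, and genes
with fewer than 100 reads summed over all samples are removed before
testing (inclusive boundary: exactly 100 is kept).

## Rhythm detection

### Test statistic

For each gene, the per-sample counts are compared against cosine reference
waveforms `cos(2π(t − L)/P)` evaluated at each sample's CT, one template
per lag `L` on the grid `{0, lag_step, …, P − lag_step}` (default lag_step
4 h; a 2-h half-interval grid is available). Replicates share template
values, so each template partitions the samples into tie groups. The
statistic per lag is Kendall's `S = C − D` over sample pairs; the reported
correlation is tau-b. The best lag (argmax S, ties broken to the earliest
lag) gives the phase estimate, on the lag grid's resolution.

### Exact null and p-values

Under permutation of tie-free data against a template with tie groups of
sizes `c₁…c_g`, the number `T` of concordant between-group pairs follows
the distribution whose generating polynomial is the Gaussian multinomial
`[n; c₁,…,c_g]_q` (the interleaving-inversions polynomial), and
`S = 2T − M` with `M` the number of between-group pairs. The polynomial is
built by exact integer convolution, so the null is exact at any `n` — the
test suite verifies it against brute-force enumeration of all orderings up
to n = 8, tied and untied. The gene's p-value is
`min(1, B · P(S ≥ s_best))` with Bonferroni factor `B` equal to the number
of lag alternatives (6 by default; sign alternatives need no extra factor
because `−cos(t − L) = cos(t − (L + 12))` is already on the grid). `B` is
configurable so alternative conventions can be compared.

### Ties in the data

Integer counts produce ties, which shrink `S` toward zero. The
genome-scale default evaluates the tied `S` against the tie-free exact
null — conservative, and what the classical implementation of this test
family does. A `tie_policy="permutation"` mode instead estimates the same
tail by seeded Monte-Carlo permutation of the gene's own values (default
10⁵ draws, add-one estimator), conditioning exactly on its tie pattern;
it is the reference behaviour for tie-heavy data but ~10⁴× slower, so it
is applied per gene rather than genome-wide. Under the default
convention, 2,000 simulated flat genes give a p < 0.05 rate of ≈ 0.04–0.05
(the Bonferroni union over positively correlated lags is mildly
conservative, ties slightly more so); this calibration is asserted in the
acceptance tests rather than assumed.

### Amplitude, classification

Amplitude is half the range of per-timepoint medians, in expression units —
a deliberate simplification; a Hodges–Lehmann variant (median of
peak-half/trough-half pairwise differences, halved) is available behind
`amplitude_method="hodges_lehmann"`. Constant series are flagged degenerate
with p = 1 and amplitude 0. Genes are labelled *rhythmic* when BH-adjusted
q < 0.05, *arrhythmic* when p > 0.5 (a deliberately conservative
non-cycling call), otherwise *indeterminate*. BH correction is applied
within each population's transcriptome.

## Differential rhythmicity (S_DR)

For a gene and an ordered population pair (1, 2):
Δperiodicity = `log p₁ − log p₂`, Δamplitude = `log₂ A₂ − log₂ A₁`; each Δ
is z-scored against the empirical mean/SD over the included genes of that
same pair (not pooled across pairs), and `S_DR = (Z_P + Z_R)/2`. Genes
enter when cycling p < 1 in either population (kept verbatim as the default
inclusion filter). With this orientation, positive S_DR means population 2
is more rhythmic; the pipeline passes (cave, surface) so that "more
rhythmic in surface" is positive. Writing Δamplitude as a difference of
logs makes the pair-swap antisymmetry bit-exact.

Design choices where the procedure was genuinely open:

- **Zero amplitudes** make the log-ratio infinite; they are floored at half
  the smallest positive amplitude observed across both tables, recorded in
  the result's `attrs` per run.
- **Tail convention**: p-values come from a Gaussian fitted to the
  empirical S_DR values; the default reported tail is the upper
  (reference-more-rhythmic) one, with lower and two-sided available.
- Degenerate cases (all Δ equal; zero SD) yield z = 0 / p = 1 with a
  warning rather than an error.

Loss sets relative to the reference population: *lost-in-all* (rhythmic in
the reference, arrhythmic in every comparison population),
*lost-in-at-least-one*, *rhythmic-in-all*. Set overlaps are tested with the
upper-tail hypergeometric; paired cycling-p comparisons over a gene set
(e.g. annotated clock genes) use the Wilcoxon signed-rank test with zero
differences dropped.

## Circular phase statistics

`circular_phase_distance(a, b)` wraps `b − a` into `(−P/2, P/2]`; the
antipodal tie (exactly half a period) is deterministically assigned
`+P/2` from either direction and flagged — the one documented asymmetry of
the distance. Population shifts are computed over genes with cycling
p < 0.05 in both populations and tested with the signed-rank statistic
(zero-difference-drop convention). Phase resolution equals the rhythm
detector's lag grid, so individual shifts are multiples of the lag step;
the mean shift is still an unbiased estimate of a planted sub-grid delay.
Phase histograms tile `[0, P)` and annotate bins subjective day/night by
bin midpoint against a default CT0–14 day / CT14–24 night split (a 14:10
rearing cycle).

## Promoter and motif analysis

Promoters are `[TSS − 1000, TSS + 200)` on the forward strand and the
mirror-image window, reverse-complemented, for minus-strand genes; windows
clipped at contig edges are flagged. Population-specific promoters are
built by substituting each population's major allele (frequency > 0.5) into
the reference window; simple indels remap coordinates, overlapping indels
are rejected, and every substitution is logged.

PWMs are `(count + pseudocount·background)/(total + pseudocount)` per
position. Scanning scores each window with the log2-odds matrix; the score
p-value is the exact probability that a background-drawn word scores at
least as high, from a dynamic programme over per-position scores
discretized onto a 10⁴-bin grid (p assigned from the bin lower edge, which
is conservative; matches brute-force enumeration for widths ≤ 6). Windows
containing N are skipped; reverse-strand hits are reported in forward
coordinates; the default reporting threshold is p < 1e-4. Note a perfect
width-6 consensus cannot clear that threshold under a uniform background
(its minimum p is 4⁻⁶ ≈ 2.4e-4), so the shipped E-box/RRE/D-box fixtures —
synthetic consensus-derived stand-ins, not database matrices — use widths
≥ 8.

Phase enrichment of motif targets: sliding circular windows (default 6 h
wide, 2-h step — unstated in the source design, chosen as 1.5× the sampling
interval with half-interval steps; both configurable), two-sided Fisher
exact test of (has motif) × (peaks in window); windows with an empty margin
report p = 1 with a flag. Cross-population motif comparison lists genes
with a hit in the reference and none in the alternate promoter, plus a
two-sided Fisher test of presence by population (so identical or balanced
presence gives exactly p = 1).

## Population genetics

Genotypes are diploid alternate-allele counts with missing data excluded
site-wise. Per-site π is the unbiased `(n/(n−1))·2p(1−p)`; per-gene π and
d_XY divide the sum over variant sites by the coding-interval length.
F_ST is the Weir–Cockerham (1984) two-population estimator; per-gene
aggregation is the ratio of averages `Σa/Σ(a+b+c)` (less biased than
averaging per-site ratios). Sites with fewer than two called diploids in
either population, or monomorphic across both, contribute nothing and are
counted as excluded. A fixed difference with no within-population
heterozygosity gives exactly 1; raw negative estimates are retained in the
tables. Outliers are the largest 5% of per-gene values (threshold = k-th
largest with k = ⌈qn⌉; ties at the threshold are all flagged).
High-frequency cave-specific variants require frequency ≥ 0.8 (inclusive —
the source's two statements of this rule differ at the boundary and the
inclusive reading is adopted) in at least one cave population and
frequency exactly 0, supported by at least 2 called alleles, in the surface
population. The relaxed-selection set test draws focal-size gene sets
without replacement (default 18 genes, 1,000 permutations) and reports the
add-one (Phipson–Smyth) p, which is bounded below by `1/(n_perm+1)` and
converges to the hypergeometric tail.

Coordinates: VCF positions are 1-based; all internal intervals are 0-based
half-open; translation happens only in the I/O adapters.

## Synthetic-data generator

The generator defines the testbed, not the biology:

- **Counts**: negative binomial with mean
  `exp(baseline + amplitude·cos(2π(t − phase)/P))` and variance
  `μ + φμ²` (dispersion φ default 0.05, baselines log-uniform on [3, 6] —
  tens to hundreds of counts, the range that survives the 100-count
  filter). Amplitude is 0 iff the gene is non-rhythmic. The count-noise
  family of real data is unknown; NB is the standard stand-in.
- **Promoters**: i.i.d. background bases (default uniform 0.25,
  configurable) with motif consensus sequences planted at recorded offsets
  (forward strand) for genes whose phase falls in a motif's window.
- **Genotypes**: Balding–Nichols allele frequencies around a uniform
  ancestral frequency with F equal to the target differentiation, binomial
  diploid genotypes, independent sites (no linkage — sufficient for testing
  estimators, a documented simplification), grouped into consecutive coding
  intervals.
- **Relaxed flags**: independent Bernoulli flags plus a without-replacement
  focal set.

All randomness descends from one top-level seed through named SHA-256
substreams, so identical (seed, config) runs are byte-identical. Truth
tables are emitted separately and never read by analysis stages.

What the generator does *not* emulate — and hence what passing tests do not
demonstrate about real data: gene–gene correlation, library-size and batch
effects, non-sinusoidal waveforms, linkage disequilibrium, demographic
structure beyond a single differentiation parameter, and any entrainment
covariate (the emulated design fed animals ad libitum precisely to avoid
food entrainment, so none is simulated).

## Problem sizes and numerical choices

Default verification sizes: 2,000 flat genes for calibration, 500 planted
rhythmic genes (amplitude 1.0 log-units, dispersion 0.05) for recovery, 600
genes for S_DR discrimination, 120 for phase-shift recovery, 20 seeds ×
250 promoters for enrichment localisation, 1,000–2,000 sites for the
F_ST checks and 10⁵ draws for the permutation-vs-hypergeometric
comparison — sizes at which the Monte-Carlo error of each check is well
below its acceptance band. Score discretization is 10⁴ bins; template
values are rounded to 12 decimals before tie-grouping; p-values are clipped
at 1e-300 before logs in S_DR.

## Known limitations

- Phase is estimated on the lag grid; sub-grid phase (and amplitude from a
  fitted waveform) are not provided.
- The arrhythmic call (p > 0.5) is deliberately conservative; with the
  exact, mildly conservative cycling p-values, a truly flat gene is
  labelled arrhythmic only ~65% of the time under the default conditions.
  Consequently "lost in **all** k comparison populations" has sensitivity
  ≈ 0.65^k for genuine complete losses (~28% at k = 3) — it is a
  high-specificity set by construction. `lost_in_at_least_one` is the
  sensitive counterpart (> 95% at k = 3).
- The Gaussian fit behind S_DR p-values is an approximation to an
  empirical, heavy-tailed score distribution; its q-values are best treated
  as a ranking.
- The Weir–Cockerham implementation is two-population; multi-population
  variance components are not implemented.
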