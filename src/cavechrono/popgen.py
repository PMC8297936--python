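"""Per-gene population-genetic summaries and selection-related set tests.

Diversity and differentiation are computed per coding interval from diploid
genotype tables: nucleotide diversity pi (unbiased per-site expected
heterozygosity summed over variants and divided by coding length), the
two-population Weir & Cockerham (1984) F_ST as a per-gene ratio of averages
sum(a)/sum(a+b+c), and absolute divergence d_XY. On top sit the study's
screens: top-quantile F_ST outlier flags, the high-frequency cave-specific
variant filter (frequency >= 0.8 in at least one cave population and absent
from the surface population), and the permutation null for relaxed-selection
gene-set enrichment (random focal sets drawn without replacement, add-one
p estimator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import substream

__all__ = [
    "GenotypeTable",
    "allele_frequencies",
    "nucleotide_diversity",
    "weir_cockerham_fst",
    "dxy",
    "popgen_table",
    "fst_outliers",
    "high_frequency_variants",
    "permutation_set_enrichment",
]

MISSING = -1


@dataclass
class GenotypeTable:
    """Sites x individuals diploid genotype matrix with population and gene maps.

    ``genotypes`` holds alternate-allele counts 0/1/2 with -1 for missing.
    ``sites`` has columns contig, pos (1-based, VCF convention), ref, alt
    and gene; ``gene_intervals`` gives each gene's coding interval as
    0-based half-open (gene, contig, start, end).
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    pop_map: Mapping[str, str]
    gene_intervals: pd.DataFrame

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape must be (n_sites, n_samples)")
        if not np.isin(g, [MISSING, 0, 1, 2]).all():
            raise ValueError("genotypes must be 0, 1, 2 or -1 (missing)")
        unknown = [s for s in self.samples if s not in self.pop_map]
        if unknown:
            raise ValueError(f"samples without a population: {unknown[:5]}")
        self.genotypes = g.astype(np.int8)

    def population_columns(self, population: str) -> np.ndarray:
        cols = np.array([i for i, s in enumerate(self.samples)
                         if self.pop_map[s] == population])
        if len(cols) == 0:
            raise KeyError(f"unknown or empty population {population!r}")
        return cols

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.pop_map[s] for s in self.samples))

    def gene_length(self, gene: str) -> int:
        row = self.gene_intervals.set_index("gene").loc[gene]
        return int(row["end"] - row["start"])


def _freq_and_called(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    called = g != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return freq, n_alleles


def allele_frequencies(table: GenotypeTable, population: str) -> pd.DataFrame:
    """Per-site alternate-allele frequency over called genotypes.

    All-missing sites get frequency NaN and a ``defined=False`` flag.
    """
    g = table.genotypes[:, table.population_columns(population)]
    freq, n_alleles = _freq_and_called(g)
    return pd.DataFrame(
        {
            "contig": table.sites["contig"].to_numpy(),
            "pos": table.sites["pos"].to_numpy(),
            "gene": table.sites["gene"].to_numpy(),
            "freq": freq,
            "n_called_alleles": n_alleles,
            "defined": n_alleles > 0,
        }
    )


def nucleotide_diversity(table: GenotypeTable, population: str) -> pd.DataFrame:
    """Per-gene pi: sum over variant sites of ``(n/(n-1)) * 2p(1-p)``
    divided by the gene's coding length (n = called alleles at the site).
    Sites with fewer than two called alleles are skipped."""
    freqs = allele_frequencies(table, population)
    n = freqs["n_called_alleles"].to_numpy(dtype=float)
    p = freqs["freq"].to_numpy()
    ok = n >= 2
    site_pi = np.zeros(len(freqs))
    site_pi[ok] = (n[ok] / (n[ok] - 1)) * 2 * p[ok] * (1 - p[ok])
    per_site = freqs[["gene"]].assign(site_pi=site_pi)
    sums = per_site.groupby("gene", sort=False)["site_pi"].sum()
    lengths = table.gene_intervals.set_index("gene")["end"] - table.gene_intervals.set_index("gene")["start"]
    out = pd.DataFrame({"gene": lengths.index})
    out["pi"] = (sums.reindex(lengths.index).fillna(0.0) / lengths).to_numpy()
    return out


def _wc_components(gA: np.ndarray, gB: np.ndarray):
    """Weir & Cockerham (1984) per-site variance components (a, b, c) for
    two populations of diploids, plus a usable-site mask."""
    r = 2.0
    fA, allelesA = _freq_and_called(gA)
    fB, allelesB = _freq_and_called(gB)
    nA, nB = allelesA / 2.0, allelesB / 2.0  # called diploids
    usable = (nA >= 2) & (nB >= 2)

    hA = np.where(gA != MISSING, gA == 1, 0).sum(axis=1) / np.maximum(nA, 1)
    hB = np.where(gB != MISSING, gB == 1, 0).sum(axis=1) / np.maximum(nB, 1)

    n_bar = (nA + nB) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (nA**2 + nB**2) / (r * n_bar)) / (r - 1)
        p_bar = (nA * fA + nB * fB) / (r * n_bar)
        s2 = (nA * (fA - p_bar) ** 2 + nB * (fB - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (nA * hA + nB * hB) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2

    # monomorphic-across-both sites contribute nothing
    poly = usable & ~((p_bar <= 0) | (p_bar >= 1)) | (usable & (h_bar > 0))
    for arr in (a, b, c):
        arr[~poly] = 0.0
        np.nan_to_num(arr, copy=False)
    return a, b, c, poly


def weir_cockerham_fst(
    table: GenotypeTable, pop_a: str, pop_b: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site WC84 components and per-gene ratio-of-averages F_ST.

    Returns ``(per_site, per_gene)``: per_site carries the a, b, c
    components (zero at sites monomorphic across both populations or with
    fewer than two called diploids in either — those are excluded from the
    sums, with exclusion counts reported per gene); per_gene carries
    ``fst = sum(a) / sum(a+b+c)`` (NaN when no usable polymorphic site).
    """
    gA = table.genotypes[:, table.population_columns(pop_a)]
    gB = table.genotypes[:, table.population_columns(pop_b)]
    a, b, c, poly = _wc_components(gA, gB)
    per_site = pd.DataFrame(
        {
            "gene": table.sites["gene"].to_numpy(),
            "pos": table.sites["pos"].to_numpy(),
            "a": a,
            "b": b,
            "c": c,
            "used": poly,
        }
    )
    grouped = per_site.groupby("gene", sort=False)
    sums = grouped[["a", "b", "c"]].sum()
    used = grouped["used"].sum()
    denom = sums["a"] + sums["b"] + sums["c"]
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, sums["a"] / denom, np.nan)
    per_gene = pd.DataFrame(
        {
            "gene": sums.index,
            "fst": fst,
            "n_sites_used": used.to_numpy(),
            "n_sites_excluded": (grouped.size() - used).to_numpy(),
        }
    ).reset_index(drop=True)
    return per_site, per_gene


def dxy(table: GenotypeTable, pop_a: str, pop_b: str) -> pd.DataFrame:
    """Per-gene absolute divergence: per-site
    ``pA(1-pB) + pB(1-pA)`` summed over variants / coding length.
    Sites with an undefined frequency in either population are skipped
    (count reported)."""
    fa = allele_frequencies(table, pop_a)
    fb = allele_frequencies(table, pop_b)
    ok = fa["defined"].to_numpy() & fb["defined"].to_numpy()
    pA, pB = fa["freq"].to_numpy(), fb["freq"].to_numpy()
    site_d = np.zeros(len(fa))
    site_d[ok] = pA[ok] * (1 - pB[ok]) + pB[ok] * (1 - pA[ok])
    per_site = fa[["gene"]].assign(site_dxy=site_d, skipped=~ok)
    grouped = per_site.groupby("gene", sort=False)
    iv = table.gene_intervals.set_index("gene")
    lengths = iv["end"] - iv["start"]
    sums = grouped["site_dxy"].sum().reindex(lengths.index).fillna(0.0)
    skipped = grouped["skipped"].sum().reindex(lengths.index).fillna(0).astype(int)
    return pd.DataFrame(
        {"gene": lengths.index, "dxy": (sums / lengths).to_numpy(),
         "n_sites_skipped": skipped.to_numpy()}
    )


def popgen_table(
    table: GenotypeTable,
    pairs: Sequence[tuple[str, str]] | None = None,
    outlier_quantile: float = 0.05,
) -> pd.DataFrame:
    """Per-gene summary: pi per population, F_ST and d_XY per pair, and
    top-quantile F_ST outlier flags (per pair and any-pair union)."""
    pops = table.populations
    if pairs is None:
        pairs = [(pops[0], p) for p in pops[1:]]
    out = table.gene_intervals[["gene"]].copy()
    for pop in pops:
        out[f"pi_{pop}"] = nucleotide_diversity(table, pop).set_index("gene").reindex(out["gene"])["pi"].to_numpy()
    flag_cols = []
    for pa, pb in pairs:
        tag = f"{pa}_{pb}"
        _, per_gene = weir_cockerham_fst(table, pa, pb)
        out[f"fst_{tag}"] = per_gene.set_index("gene").reindex(out["gene"])["fst"].to_numpy()
        out[f"dxy_{tag}"] = dxy(table, pa, pb).set_index("gene").reindex(out["gene"])["dxy"].to_numpy()
        flags = fst_outliers(out[f"fst_{tag}"], outlier_quantile)
        out[f"outlier_{tag}"] = flags
        flag_cols.append(f"outlier_{tag}")
    out["outlier_any"] = out[flag_cols].any(axis=1)
    return out


def fst_outliers(values, quantile: float = 0.05) -> np.ndarray:
    """Flag the largest ``quantile`` fraction of per-gene values.

    The threshold is the k-th largest value with k = ceil(quantile * n)
    over non-NaN entries; ties at the threshold are all flagged. Requires
    at least 20 genes.
    """
    v = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    finite = np.isfinite(v)
    n = int(finite.sum())
    if n < 20:
        raise ValueError("need at least 20 genes with defined values")
    k = max(1, math.ceil(quantile * n))
    threshold = np.sort(v[finite])[::-1][k - 1]
    return finite & (v >= threshold)


def high_frequency_variants(
    frequencies: pd.DataFrame,
    cave_populations: Sequence[str],
    surface_population: str,
    threshold: float = 0.8,
    min_called_alleles: int = 2,
) -> pd.DataFrame:
    """Variants at frequency >= ``threshold`` in at least one cave
    population and absent (frequency exactly 0, with at least
    ``min_called_alleles`` called alleles) from the surface population.

    ``frequencies`` must have one frequency column per population plus,
    optionally, ``n_called_<surface>`` for the missingness guard.
    """
    for pop in [*cave_populations, surface_population]:
        if pop not in frequencies.columns:
            raise ValueError(f"no frequency column for population {pop!r}")
    cave_hit = np.zeros(len(frequencies), dtype=bool)
    for pop in cave_populations:
        cave_hit |= frequencies[pop].to_numpy() >= threshold
    surf = frequencies[surface_population].to_numpy()
    absent = surf == 0
    ncol = f"n_called_{surface_population}"
    if ncol in frequencies.columns:
        absent &= frequencies[ncol].to_numpy() >= min_called_alleles
    return frequencies[cave_hit & absent].reset_index(drop=True)


def permutation_set_enrichment(
    flags: Mapping[str, bool] | pd.Series,
    focal_size: int,
    observed_count: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Permutation null for gene-set enrichment of boolean flags.

    Draws ``focal_size`` genes without replacement ``n_perm`` times and
    counts how many draws contain at least ``observed_count`` flagged
    genes; p uses the add-one estimator ``(1 + hits) / (n_perm + 1)`` so it
    is never zero. Returns ``(p, null_counts)``.
    """
    flag_arr = pd.Series(flags).to_numpy(dtype=bool)
    n_genes = len(flag_arr)
    if focal_size > n_genes:
        raise ValueError("focal_size exceeds the number of genes")
    if observed_count > focal_size:
        raise ValueError("observed_count exceeds focal_size")
    rng = substream(seed, "permutation-enrichment")
    null_counts = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:  # chunked to bound memory at genome scale
        k = min(5000, n_perm - done)
        draws = np.argsort(rng.random((k, n_genes)), axis=1)[:, :focal_size]
        null_counts[done : done + k] = flag_arr[draws].sum(axis=1)
        done += k
    p = (1 + int(np.sum(null_counts >= observed_count))) / (n_perm + 1)
    return float(p), null_counts
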