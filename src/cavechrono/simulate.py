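"""Synthetic inputs emulating the multi-population circadian study design.

Everything the downstream stages consume can be generated here with known
ground truth: negative-binomial count matrices whose log-means follow
population-specific cosine signals, promoter sequences with motifs planted
in phase windows, two-population diploid genotype matrices of controlled
differentiation, and per-gene relaxed-selection flag tables.

The default expression design mirrors the study: four populations (one
surface reference, three cave), six timepoints at 4-h spacing across one
24-h cycle, six replicates per timepoint. All randomness descends from a
single top-level seed through named substreams, so identical (seed, truth)
pairs reproduce identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DEFAULT_DESIGN, ExpressionMatrix, SamplingDesign, substream

__all__ = [
    "GeneTruth",
    "SimulationTruth",
    "PlantingRule",
    "make_gene_truth",
    "simulate_expression",
    "simulate_promoters",
    "simulate_genotypes",
    "simulate_relaxed_flags",
]

DEFAULT_POPULATIONS = ("Surface", "Pachon", "Tinaja", "Molino")

TRUTH_COLUMNS = ["gene", "population", "rhythmic", "baseline", "amplitude", "phase", "dispersion"]


@dataclass(frozen=True)
class GeneTruth:
    """Planted generative parameters for one gene in one population.

    ``baseline`` is the mean log-expression, ``amplitude`` the log-scale
    half peak-to-trough swing, ``phase`` the peak time in hours and
    ``dispersion`` the negative-binomial overdispersion
    (variance = mu + dispersion * mu^2). ``amplitude`` is zero iff the gene
    is not rhythmic in that population.
    """

    gene: str
    population: str
    rhythmic: bool
    baseline: float
    amplitude: float
    phase: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"gene {self.gene}: amplitude must be >= 0")
        if (self.amplitude == 0) != (not self.rhythmic):
            raise ValueError(f"gene {self.gene}: amplitude must be 0 iff not rhythmic")
        if self.dispersion < 0:
            raise ValueError(f"gene {self.gene}: dispersion must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside simulated inputs (never read by the
    pipeline stages themselves)."""

    design: SamplingDesign | None = None
    gene_truth: pd.DataFrame | None = None
    planted_motifs: pd.DataFrame | None = None
    target_differentiation: float | None = None
    relaxed_flags: pd.DataFrame | None = None
    focal_genes: list[str] | None = None
    extras: dict = field(default_factory=dict)


def truth_frame(records: Sequence[GeneTruth]) -> pd.DataFrame:
    rows = [
        (t.gene, t.population, t.rhythmic, t.baseline, t.amplitude, t.phase, t.dispersion)
        for t in records
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def make_gene_truth(
    n_genes: int = 500,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
    *,
    rhythmic_fraction: float = 0.2,
    loss_fraction: float = 0.0,
    amplitude: float = 1.0,
    baseline_range: tuple[float, float] = (3.0, 6.0),
    dispersion: float = 0.05,
    phase_shift: Mapping[str, float] | None = None,
    period: float = 24.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a study-like truth table.

    A ``rhythmic_fraction`` of genes oscillates in the first (reference)
    population; of those, ``loss_fraction`` lose rhythmicity entirely
    (amplitude -> 0) in every non-reference population. ``phase_shift``
    optionally delays the peak of each non-reference population by a fixed
    number of hours (the planted analogue of the later peaks observed in
    cave populations). Phases are drawn uniformly on [0, period).
    """
    rng = substream(seed, "gene-truth")
    genes = [f"g{i:05d}" for i in range(n_genes)]
    rhythmic = rng.random(n_genes) < rhythmic_fraction
    lost = rhythmic & (rng.random(n_genes) < loss_fraction)
    baselines = rng.uniform(*baseline_range, size=n_genes)
    phases = rng.uniform(0, period, size=n_genes)
    shift = phase_shift or {}

    records = []
    ref = populations[0]
    for gi, gene in enumerate(genes):
        for pop in populations:
            is_ref = pop == ref
            rhy = bool(rhythmic[gi]) and (is_ref or not lost[gi])
            amp = amplitude if rhy else 0.0
            ph = (phases[gi] + (0.0 if is_ref else shift.get(pop, 0.0))) % period
            records.append(
                GeneTruth(gene, pop, rhy, float(baselines[gi]), amp, float(ph), dispersion)
            )
    return truth_frame(records)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Negative binomial with variance mu + dispersion*mu^2 (Poisson at 0)."""
    out = np.empty(mean.shape, dtype=np.int64)
    pois = dispersion == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        size = 1.0 / dispersion[~pois]
        p = size / (size + mean[~pois])
        out[~pois] = rng.negative_binomial(size, p)
    return out


def simulate_expression(
    truth: pd.DataFrame,
    design: SamplingDesign | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Draw a count matrix from planted cosine signals under NB noise.

    Counts for gene g, population c, time t are NB with mean
    ``exp(baseline + amplitude * cos(2*pi*(t - phase)/period))``. The
    default design (6 timepoints x 4 h x 6 replicates, period 24 h) is used
    when ``design`` is omitted. Identical (seed, truth) reproduce identical
    matrices.
    """
    if design is None:
        design = DEFAULT_DESIGN
    bad = truth[~np.isfinite(truth[["baseline", "amplitude", "phase", "dispersion"]]).all(axis=1)]
    if len(bad):
        raise ValueError(f"non-finite truth parameters for gene(s): {sorted(bad['gene'].unique())}")
    if (truth["dispersion"] < 0).any():
        raise ValueError("dispersions must be >= 0")
    if truth.duplicated(["gene", "population"]).any():
        raise ValueError("each (gene, population) must appear exactly once in truth")

    genes = list(dict.fromkeys(truth["gene"]))
    populations = list(dict.fromkeys(truth["population"]))
    times = design.sample_times

    blocks, columns, meta_rows = [], [], []
    for pop in populations:
        sub = truth[truth["population"] == pop].set_index("gene").loc[genes]
        mu = np.exp(
            sub["baseline"].to_numpy()[:, None]
            + sub["amplitude"].to_numpy()[:, None]
            * np.cos(2 * np.pi * (times[None, :] - sub["phase"].to_numpy()[:, None]) / design.period)
        )
        disp = np.broadcast_to(sub["dispersion"].to_numpy()[:, None], mu.shape)
        rng = substream(seed, "expression", pop)
        blocks.append(_nb_draw(rng, mu, disp))
        names = design.sample_names(pop)
        columns.extend(names)
        for name, t in zip(names, times):
            meta_rows.append((name, pop, float(t), int(name.rsplit("_r", 1)[1])))

    counts = pd.DataFrame(np.hstack(blocks), index=pd.Index(genes, name="gene"), columns=columns)
    meta = pd.DataFrame(meta_rows, columns=["sample", "population", "CT", "replicate"]).set_index("sample")
    em = ExpressionMatrix(counts, meta, design)
    return em, SimulationTruth(design=design, gene_truth=truth.copy())


# ---------------------------------------------------------------------------
# promoters


@dataclass(frozen=True)
class PlantingRule:
    """Plant ``motif`` (by consensus) into promoters of genes whose phase
    falls in ``window`` (circular, hours), with probability ``probability``."""

    phase_window: tuple[float, float]
    probability: float = 1.0

    def contains(self, phase: float, period: float = 24.0) -> bool:
        lo, hi = self.phase_window
        width = hi - lo if hi > lo else hi - lo + period
        return (phase - lo) % period < width


def simulate_promoters(
    gene_phases: Mapping[str, float],
    motif_library: Mapping[str, "object"],
    planting_rule: Mapping[str, PlantingRule],
    length: int = 1200,
    seed: int = 0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    period: float = 24.0,
):
    """Random promoters with motif consensus sequences planted by phase.

    Background bases are i.i.d. from ``background`` over ACGT. For every
    gene whose phase lies in a motif's planting window, that motif's
    consensus is inserted (overwriting background) at a uniformly random
    offset on the forward strand with the rule's probability; offsets are
    recorded in the returned truth table (gene, motif, offset, strand).

    Returns ``(PromoterSet, planted_truth)``.
    """
    from .motifs import PromoterRecord, PromoterSet

    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1) > 1e-9 or (bg < 0).any():
        raise ValueError("background must be 4 probabilities summing to 1")
    consensi = {name: _consensus_of(m) for name, m in motif_library.items()}
    widest = max(len(c) for c in consensi.values())
    if length < widest:
        raise ValueError(f"promoter length {length} shorter than widest motif ({widest})")
    for name, rule in planting_rule.items():
        lo, hi = rule.phase_window
        if not (0 <= lo % period < period and 0 <= hi % period <= period):
            raise ValueError(f"planting window for {name} outside [0, period)")

    rng = substream(seed, "promoters")
    alphabet = np.array(list("ACGT"))
    records, truth_rows = {}, []
    for gene in sorted(gene_phases):
        phase = gene_phases[gene]
        seq = alphabet[rng.choice(4, size=length, p=bg)]
        for motif in sorted(planting_rule):
            rule = planting_rule[motif]
            if rule.contains(phase, period) and rng.random() < rule.probability:
                cons = consensi[motif]
                offset = int(rng.integers(0, length - len(cons) + 1))
                seq[offset : offset + len(cons)] = list(cons)
                truth_rows.append((gene, motif, offset, "+"))
        records[gene] = PromoterRecord(gene=gene, seq="".join(seq))
    truth = pd.DataFrame(truth_rows, columns=["gene", "motif", "offset", "strand"])
    return PromoterSet(records), truth


def _consensus_of(motif) -> str:
    if isinstance(motif, str):
        return motif
    return motif.consensus  # PWM objects expose a consensus string


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    n_sites: int,
    sample_sizes: Mapping[str, int],
    target_fst: float = 0.1,
    seed: int = 0,
    *,
    gene_length: int = 1000,
    sites_per_gene: int | None = None,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
):
    """Two(or more)-population diploid genotypes of controlled differentiation.

    Per-site ancestral frequencies are uniform on ``ancestral_range``;
    population frequencies follow the Balding-Nichols model with
    F = ``target_fst`` (Beta(p(1-F)/F, (1-p)(1-F)/F)), so the expected
    Weir-Cockerham differentiation is the planted F. Genotypes are
    independent binomial(2, p_pop) draws — no linkage. Sites are laid on a
    single contig and grouped into consecutive genes of ``gene_length``
    coding bases (``sites_per_gene`` sites each; defaults to an even split).

    Returns ``(GenotypeTable, SimulationTruth)`` with the planted F
    recorded in the truth.
    """
    from .popgen import GenotypeTable

    if any(n < 2 for n in sample_sizes.values()):
        raise ValueError("need at least 2 diploid individuals per population")
    if not 0 <= target_fst < 1:
        raise ValueError("target_fst must lie in [0, 1)")
    rng = substream(seed, "genotypes")

    p_anc = rng.uniform(*ancestral_range, size=n_sites)
    pops = list(sample_sizes)
    freqs = {}
    for pop in pops:
        if target_fst == 0:
            freqs[pop] = p_anc.copy()
        else:
            a = p_anc * (1 - target_fst) / target_fst
            b = (1 - p_anc) * (1 - target_fst) / target_fst
            freqs[pop] = rng.beta(a, b)

    samples, pop_map, g_cols = [], {}, []
    for pop in pops:
        for i in range(sample_sizes[pop]):
            name = f"{pop}_{i:02d}"
            samples.append(name)
            pop_map[name] = pop
            g_cols.append(rng.binomial(2, freqs[pop]))
    G = np.stack(g_cols, axis=1).astype(np.int8)

    spg = sites_per_gene if sites_per_gene is not None else min(n_sites, 50)
    if spg > gene_length:
        raise ValueError("sites_per_gene cannot exceed gene_length")
    n_genes = int(np.ceil(n_sites / spg))
    gene_ids = np.repeat([f"g{i:05d}" for i in range(n_genes)], spg)[:n_sites]
    # place each gene in its own gene_length window, sites evenly spread
    positions = np.empty(n_sites, dtype=int)
    intervals = []
    for i in range(n_genes):
        idx = np.flatnonzero(gene_ids == f"g{i:05d}")
        start = i * (gene_length + 100)
        offs = np.sort(rng.choice(gene_length, size=len(idx), replace=False))
        positions[idx] = start + offs
        intervals.append((f"g{i:05d}", "chr1", start, start + gene_length))

    sites = pd.DataFrame(
        {
            "contig": "chr1",
            "pos": positions + 1,  # VCF-style 1-based
            "ref": rng.choice(list("ACGT"), size=n_sites),
            "gene": gene_ids,
        }
    )
    sites["alt"] = [
        {"A": "G", "C": "T", "G": "A", "T": "C"}[r] for r in sites["ref"]
    ]
    gene_intervals = pd.DataFrame(intervals, columns=["gene", "contig", "start", "end"])

    table = GenotypeTable(
        sites=sites[["contig", "pos", "ref", "alt", "gene"]],
        genotypes=G,
        samples=samples,
        pop_map=pop_map,
        gene_intervals=gene_intervals,
    )
    truth = SimulationTruth(
        target_differentiation=target_fst,
        extras={"allele_frequencies": pd.DataFrame(freqs)},
    )
    return table, truth


def simulate_relaxed_flags(
    n_genes: int,
    relaxed_fraction: float,
    focal_set_size: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene boolean relaxed-selection flags plus a focal gene list.

    Each gene is flagged independently with probability ``relaxed_fraction``;
    the focal set (e.g., the 18 clock-gene orthologs) is sampled without
    replacement from all genes.
    """
    if not 0 <= relaxed_fraction <= 1:
        raise ValueError("relaxed_fraction must lie in [0, 1]")
    if focal_set_size > n_genes:
        raise ValueError("focal_set_size cannot exceed n_genes")
    rng = substream(seed, "relaxed-flags")
    genes = [f"g{i:05d}" for i in range(n_genes)]
    flags = pd.DataFrame(
        {"gene": genes, "relaxed": rng.random(n_genes) < relaxed_fraction}
    )
    focal = sorted(rng.choice(genes, size=focal_set_size, replace=False).tolist())
    return flags, focal
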