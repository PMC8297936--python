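"""End-to-end orchestration of the comparative circadian analysis.

One :class:`PipelineConfig` drives every stage: (optionally) simulate the
study inputs, filter low-expression genes, detect rhythmic transcripts per
population, classify and build rhythmicity-loss sets, score differential
rhythmicity per cave-surface pair, quantify phase shifts, scan promoters
and test phase enrichment of motif targets, and compute population-genetic
summaries with the permutation set-enrichment test. Each stage writes one
TSV; a single JSON summary embeds the fully resolved configuration and
seed, and identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, io, motifs, phase, popgen, rhythm, simulate
from .design import SamplingDesign

__all__ = ["PipelineConfig", "SimulationConfig", "run_pipeline"]

log = logging.getLogger("cavechrono")

_FLOAT_FMT = "%.10g"


@dataclass
class SimulationConfig:
    """Synthetic-input block emulating the study design (four populations,
    one surface reference + three caves; 6x4h timepoints, 6 replicates)."""

    n_genes: int = 500
    populations: tuple[str, ...] = simulate.DEFAULT_POPULATIONS
    rhythmic_fraction: float = 0.2
    loss_fraction: float = 0.3
    amplitude: float = 1.0
    dispersion: float = 0.05
    cave_phase_delay: float = 2.0
    promoter_length: int = 1200
    n_sites: int = 2000
    samples_per_population: int = 10
    target_fst: float = 0.2
    relaxed_fraction: float = 0.1
    focal_set_size: int = 18


@dataclass
class PipelineConfig:
    """All stage parameters; defaults mirror the study's stated constants."""

    seed: int = 0
    period: float = 24.0
    lag_step: float = 4.0
    min_total: int = 100
    fdr: float = 0.05
    arrhythmic_p: float = 0.5
    sdr_tail: str = "upper"
    phase_p_threshold: float = 0.05
    enrichment_fdr: float = 0.1
    promoter_upstream: int = 1000
    promoter_downstream: int = 200
    motif_p: float = 1e-4
    enrichment_window: float = 6.0
    enrichment_step: float = 2.0
    outlier_quantile: float = 0.05
    hf_threshold: float = 0.8
    focal_size: int = 18
    n_perm: int = 1000
    # either a simulation block or paths to real inputs
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    counts_path: str | None = None
    meta_path: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if self.simulation is None and (self.counts_path is None or self.meta_path is None):
            raise ValueError("config needs either a simulation block or input paths")
        for name, lo, hi in [
            ("fdr", 0, 1), ("arrhythmic_p", 0, 1), ("motif_p", 0, 1),
            ("outlier_quantile", 0, 1), ("hf_threshold", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}]")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns the summary dict (also written to
    ``summary.json`` in ``outdir`` alongside the per-stage TSVs)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    summary: dict = {"config": _config_dict(config), "stages": []}
    t0 = time.time()

    def stage(name):
        log.info("stage %-10s t=%.1fs", name, time.time() - t0)
        summary["stages"].append(name)

    # --- inputs -----------------------------------------------------------
    sim = config.simulation
    truth = None
    if sim is not None:
        stage("simulate")
        truth = simulate.make_gene_truth(
            n_genes=sim.n_genes,
            populations=sim.populations,
            rhythmic_fraction=sim.rhythmic_fraction,
            loss_fraction=sim.loss_fraction,
            amplitude=sim.amplitude,
            dispersion=sim.dispersion,
            phase_shift={p: sim.cave_phase_delay for p in sim.populations[1:]},
            period=config.period,
            seed=seed,
        )
        matrix, sim_truth = simulate.simulate_expression(truth, seed=seed)
        io.write_expression(matrix, out / "counts.tsv", out / "metadata.tsv")
        truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    else:
        matrix = io.read_expression(config.counts_path, config.meta_path)

    reference = matrix.populations[0]
    comparisons = matrix.populations[1:]

    # --- rhythm detection -------------------------------------------------
    stage("filter")
    matrix = rhythm.filter_low_expression(matrix, config.min_total)

    stage("rhythm")
    rtable = rhythm.rhythm_table(
        matrix, config.period, config.lag_step,
        fdr_threshold=config.fdr, arrhythmic_threshold=config.arrhythmic_p,
    )
    _write(rtable.drop(columns=["degenerate"]), out / "rhythm.tsv")
    summary["rhythmic_per_population"] = {
        pop: int(((rtable["population"] == pop) & (rtable["label"] == "rhythmic")).sum())
        for pop in matrix.populations
    }

    # --- loss sets --------------------------------------------------------
    stage("loss_sets")
    labels = {
        pop: rtable[rtable["population"] == pop].set_index("gene")["label"]
        for pop in matrix.populations
    }
    sets = differential.loss_sets(labels, reference)
    rows = [(name, g) for name, gs in sets.items() for g in sorted(gs)]
    _write(pd.DataFrame(rows, columns=["set", "gene"]), out / "loss_sets.tsv")
    summary["loss_set_sizes"] = {name: len(gs) for name, gs in sets.items()}

    # --- differential rhythmicity ----------------------------------------
    stage("sdr")
    per_pop = {pop: rtable[rtable["population"] == pop] for pop in matrix.populations}
    sdr_frames = []
    for pop in comparisons:
        scores = differential.sdr_scores(per_pop[pop], per_pop[reference])
        scores = differential.sdr_pvalues(scores, tail=config.sdr_tail)
        sdr_frames.append(scores)
    sdr_all = pd.concat(sdr_frames, ignore_index=True)
    _write(sdr_all, out / "sdr.tsv")
    top = (
        sdr_all.sort_values("S_DR", ascending=False)
        .drop_duplicates("gene").head(10)["gene"].tolist()
    )
    summary["top_sdr_genes"] = top
    summary["sdr_significant_per_pair"] = {
        f"{a}_vs_{reference}": int((df["q"] < config.fdr).sum())
        for a, df in zip(comparisons, sdr_frames)
    }

    # --- phase analysis ---------------------------------------------------
    stage("phase")
    shift_frames, shift_summary = [], {}
    for pop in comparisons:
        rec = phase.phase_shift_records(
            per_pop[reference], per_pop[pop], config.phase_p_threshold, config.period
        )
        rec.insert(1, "population", pop)
        shift_frames.append(rec)
        if len(rec) >= 6:
            mean, median, p = phase.phase_shift_test(rec)
            shift_summary[pop] = {"n": len(rec), "mean": mean, "median": median, "p": p}
        else:
            shift_summary[pop] = {"n": len(rec), "mean": None, "median": None, "p": None}
    _write(pd.concat(shift_frames, ignore_index=True), out / "phase_shifts.tsv")
    summary["phase_shift"] = shift_summary

    hist_frames = []
    for pop in matrix.populations:
        h = phase.phase_histogram(per_pop[pop], config.lag_step, config.period)
        h.insert(0, "population", pop)
        hist_frames.append(h)
    _write(pd.concat(hist_frames, ignore_index=True), out / "phase_histogram.tsv")

    # --- motif analysis ---------------------------------------------------
    if sim is not None:
        stage("motifs")
        ref_rhy = per_pop[reference]
        enrich_genes = ref_rhy[ref_rhy["q"] < config.enrichment_fdr]
        gene_phases = dict(zip(enrich_genes["gene"], enrich_genes["phase"]))
        library = motifs.builtin_motifs()
        rules = {
            "EBOX": simulate.PlantingRule((0.0, 6.0), 0.9),
            "RRE": simulate.PlantingRule((10.0, 16.0), 0.9),
            "DBOX": simulate.PlantingRule((6.0, 10.0), 0.9),
        }
        truth_phases = truth[truth["population"] == reference].set_index("gene")
        promoter_phases = {
            g: float(truth_phases.loc[g, "phase"])
            for g in truth_phases.index[truth_phases["rhythmic"]]
        }
        proms, planted = simulate.simulate_promoters(
            promoter_phases, library, rules, sim.promoter_length, seed=seed,
        )
        io.write_promoters(proms, out / "promoters.fasta")
        _write(planted, out / "promoter_truth.tsv")

        hits = motifs.scan_promoters(proms, library, config.motif_p)
        _write(hits, out / "motif_hits.tsv")
        enrich_frames = []
        best_windows = {}
        for name in library:
            flags = {g: g in set(hits[hits["motif"] == name]["gene"]) for g in gene_phases}
            enr = motifs.phase_window_enrichment(
                gene_phases, flags, config.enrichment_window,
                config.enrichment_step, config.period,
            )
            enr.insert(0, "motif", name)
            enrich_frames.append(enr)
            usable = enr[~enr["empty_cell"]]
            if len(usable):
                best = usable.loc[usable["p"].idxmin()]
                best_windows[name] = {
                    "window_start": float(best["window_start"]),
                    "window_center": float(best["window_center"]),
                    "p": float(best["p"]),
                }
        _write(pd.concat(enrich_frames, ignore_index=True), out / "motif_enrichment.tsv")
        summary["motif_best_windows"] = best_windows

    # --- population genetics ---------------------------------------------
    if sim is not None:
        stage("popgen")
        surface_pg, cave_pg = "SurfacePG", "CavePG"
        gtable, gtruth = simulate.simulate_genotypes(
            sim.n_sites,
            {surface_pg: sim.samples_per_population, cave_pg: sim.samples_per_population},
            target_fst=sim.target_fst,
            seed=seed,
        )
        io.write_vcf(gtable, out / "variants.vcf")
        io.write_population_map(gtable.pop_map, out / "population_map.tsv")
        pg = popgen.popgen_table(
            gtable, pairs=[(surface_pg, cave_pg)], outlier_quantile=config.outlier_quantile
        )
        _write(pg, out / "popgen.tsv")
        summary["fst_outlier_genes"] = sorted(pg[pg["outlier_any"]]["gene"].tolist())
        summary["mean_fst"] = float(np.nanmean(pg[f"fst_{surface_pg}_{cave_pg}"]))

        freqs = pd.DataFrame(
            {
                cave_pg: popgen.allele_frequencies(gtable, cave_pg)["freq"],
                surface_pg: popgen.allele_frequencies(gtable, surface_pg)["freq"],
                "pos": gtable.sites["pos"],
                "gene": gtable.sites["gene"],
            }
        )
        hf = popgen.high_frequency_variants(
            freqs, [cave_pg], surface_pg, config.hf_threshold
        )
        _write(hf, out / "hf_variants.tsv")
        summary["n_hf_variants"] = int(len(hf))

        flags, focal = simulate.simulate_relaxed_flags(
            sim.n_genes, sim.relaxed_fraction, config.focal_size, seed=seed
        )
        observed = int(flags.set_index("gene").loc[focal, "relaxed"].sum())
        perm_p, _ = popgen.permutation_set_enrichment(
            flags.set_index("gene")["relaxed"], config.focal_size, observed,
            config.n_perm, seed=seed,
        )
        summary["relaxed_selection"] = {
            "observed_flagged_in_focal": observed,
            "permutation_p": perm_p,
        }

    summary["seed"] = seed
    io.write_json_report(summary, out / "summary.json")
    stage("done")
    return summary


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    if d.get("simulation") is not None and not isinstance(d["simulation"], dict):
        d["simulation"] = asdict(d["simulation"])
    if d.get("simulation"):
        d["simulation"]["populations"] = list(d["simulation"]["populations"])
    return d


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
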