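"""Readers and writers for every interchange format the pipeline uses.

Counts and metadata travel as TSV, promoters and genomes as FASTA
(Bio.SeqIO), gene tables as BED-like TSV, variants as plain-text VCF
(written directly, read back through cyvcf2), PWMs in MEME minimal format
(parsed with Bio.motifs), configuration as YAML/JSON and reports as JSON.
Coordinates: VCF positions are 1-based; everything internal is 0-based
half-open — translation happens only here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ExpressionMatrix, SamplingDesign
from .motifs import PWM, PromoterRecord, PromoterSet
from .popgen import GenotypeTable

__all__ = [
    "write_counts", "read_counts", "write_metadata", "read_metadata",
    "read_expression", "write_expression",
    "write_fasta", "read_fasta", "write_promoters", "read_promoters",
    "write_gene_table", "read_gene_table",
    "write_vcf", "read_vcf", "write_population_map", "read_population_map",
    "read_meme", "write_meme",
    "write_json_report", "read_config", "write_config",
]


# ---------------------------------------------------------------------------
# counts + metadata


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    """Gene x sample TSV of non-negative integers; rejects malformed cells
    with their row/column coordinates."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = pd.DataFrame(index=df.index.rename("gene"), columns=df.columns, dtype=np.int64)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round()) | (converted < 0)
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise ValueError(
                f"{path}: non-integer count at gene {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        out[col] = converted.astype(np.int64)
    return out


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample")
    required = {"population", "CT", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return meta


def write_expression(matrix: ExpressionMatrix, counts_path, meta_path) -> None:
    write_counts(matrix.counts, counts_path)
    write_metadata(matrix.meta, meta_path)


def read_expression(counts_path, meta_path, design: SamplingDesign | None = None) -> ExpressionMatrix:
    counts = read_counts(counts_path)
    meta = read_metadata(meta_path)
    if design is None:
        cts = sorted(meta["CT"].unique())
        reps = int(meta.groupby(["population", "CT"]).size().max())
        period = 24.0 if max(cts) < 24 else float(max(cts)) + (cts[1] - cts[0])
        design = SamplingDesign(tuple(float(t) for t in cts), reps, period)
    return ExpressionMatrix(counts[meta.index], meta, design)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_promoters(promoters: PromoterSet, path) -> None:
    write_fasta(promoters.sequences(), path)


def read_promoters(path) -> PromoterSet:
    return PromoterSet(
        {name: PromoterRecord(gene=name, seq=seq) for name, seq in read_fasta(path).items()}
    )


# ---------------------------------------------------------------------------
# gene tables (BED-like)


def write_gene_table(table: pd.DataFrame, path) -> None:
    """BED-like TSV: contig, start, end, gene (+ extra columns preserved)."""
    cols = ["contig", "start", "end", "gene"]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("contig", "start", "end", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: gene table missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# VCF + population map


def write_vcf(table: GenotypeTable, path) -> None:
    """Plain-text, uncompressed VCF 4.2 with diploid GT fields."""
    contigs = list(dict.fromkeys(table.sites["contig"]))
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples))
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    for i, row in enumerate(table.sites.itertuples(index=False)):
        gts = "\t".join(gt_code[int(g)] for g in table.genotypes[i])
        lines.append(f"{row.contig}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, pop_map: Mapping[str, str], gene_intervals: pd.DataFrame) -> GenotypeTable:
    """Read a VCF through cyvcf2 into a GenotypeTable; missing GT fields
    become the missing code. Sites are assigned to the gene whose coding
    interval contains them (others get gene = '.')."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, gmat = [], []
    for var in vcf:
        counts = []
        for gt in var.genotypes:
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                counts.append(MISSING_CODE)
            else:
                counts.append(int(sum(1 for a in alleles if a > 0)))
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0] if var.ALT else "."))
        gmat.append(counts)
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    sites["gene"] = "."
    iv = gene_intervals
    for row in iv.itertuples(index=False):
        inside = (
            (sites["contig"] == row.contig)
            & (sites["pos"] - 1 >= row.start)
            & (sites["pos"] - 1 < row.end)
        )
        sites.loc[inside, "gene"] = row.gene
    return GenotypeTable(
        sites=sites,
        genotypes=np.asarray(gmat, dtype=np.int8),
        samples=samples,
        pop_map=dict(pop_map),
        gene_intervals=gene_intervals,
    )


MISSING_CODE = -1


def write_population_map(pop_map: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(pop_map), "population": list(pop_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_population_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["population"]))


# ---------------------------------------------------------------------------
# MEME PWMs


def read_meme(path) -> dict[str, PWM]:
    """Parse a MEME-format motif file into PWM objects (via Bio.motifs)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = {}
    for m in parsed:
        probs = np.array([[m.pwm[base][i] for base in "ACGT"] for i in range(m.length)])
        probs = probs / probs.sum(axis=1, keepdims=True)
        bg = np.array([m.background.get(b, 0.25) for b in "ACGT"])
        out[m.name] = PWM(name=m.name, probs=probs, background=bg)
    return out


def write_meme(pwms: Mapping[str, PWM], path) -> None:
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    bg = next(iter(pwms.values())).background if pwms else np.full(4, 0.25)
    lines.append("Background letter frequencies")
    lines.append(" ".join(f"{b} {f:.6f}" for b, f in zip("ACGT", bg)))
    lines.append("")
    for name, pwm in pwms.items():
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= 1000000 E= 0"
        )
        for row in pwm.probs:
            lines.append(" ".join(f"{v:9.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# config + reports


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return super().default(obj)


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(config: dict, path) -> None:
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(config, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
    else:
        Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
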