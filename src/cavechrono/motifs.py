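"""Promoter extraction and PWM motif analysis.

Putative promoters are the region 1 kb upstream to 200 bp downstream of the
TSS. Motif scanning is FIMO-like: sequences are scored with a log-odds
position weight matrix and each window's p-value is the probability that a
background-drawn word scores at least as high, computed from the exact
discretized score distribution (a dynamic programme over positions); hits
below p = 1e-4 are reported by default. Downstream, targets of a motif are
tested for circular phase enrichment with sliding-window Fisher exact
tests, and population-specific promoters (reference sequence with each
population's major alleles substituted) are compared for motif loss.

The shipped E-box / RRE / D-box models are synthetic consensus-derived
stand-ins for testing; production PWMs are supplied in MEME format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PWM",
    "MotifHit",
    "PromoterRecord",
    "PromoterSet",
    "pwm_from_counts",
    "consensus_pwm",
    "builtin_motifs",
    "ScorePValueTable",
    "score_pvalue_table",
    "scan_sequence",
    "scan_promoters",
    "extract_promoters",
    "apply_variants",
    "phase_window_enrichment",
    "motif_presence_comparison",
]

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

UNIFORM_BG = np.full(4, 0.25)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over ACGT (rows = positions).

    ``probs`` columns sum to one per position; zero entries are legal for
    pseudocount-free matrices but are clipped when forming log-odds scores.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        if (p < 0).any():
            raise ValueError("PWM probabilities must be non-negative")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.probs.argmax(axis=1))

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """log2 likelihood-ratio matrix; zero probabilities clipped to 1e-9."""
        bg = self.background if background is None else np.asarray(background, float)
        return np.log2(np.clip(self.probs, 1e-9, None) / bg[None, :])

    def reverse_complement(self) -> "PWM":
        return replace(self, probs=self.probs[::-1, ::-1].copy())


def pwm_from_counts(
    count_matrix,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
    name: str = "",
) -> PWM:
    """Probabilities ``(count + pseudocount*background) / (total + pseudocount)``
    per position. Rejects all-zero columns."""
    counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("count matrix must be (width, 4)")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("PWM has an all-zero position")
    bg = UNIFORM_BG if background is None else np.asarray(background, float)
    totals = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount * bg[None, :]) / (totals + pseudocount)
    return PWM(name=name, probs=probs, background=bg, pseudocount=pseudocount)


def consensus_pwm(consensus: str, name: str = "", strength: float = 100.0,
                  pseudocount: float = 1.0) -> PWM:
    """High-information PWM built from a consensus string (test fixture grade)."""
    counts = np.zeros((len(consensus), 4))
    for i, base in enumerate(consensus.upper()):
        counts[i, _ALPHABET.index(base)] = strength
    return pwm_from_counts(counts, pseudocount=pseudocount, name=name or consensus)


def builtin_motifs() -> dict[str, PWM]:
    """Synthetic consensus-derived stand-ins for the canonical circadian
    cis-elements: the CLOCK:ARNTL E-box, the ROR/NR1D response element (RRE)
    and the DBP/NFIL3 D-box. Widths are >= 8 so a perfect match can clear
    the 1e-4 scan threshold under a uniform background."""
    return {
        "EBOX": consensus_pwm("CCACGTGG", name="EBOX"),
        "RRE": consensus_pwm("AACTAGGTCA", name="RRE"),
        "DBOX": consensus_pwm("TTATGTAA", name="DBOX"),
    }


# ---------------------------------------------------------------------------
# exact score distribution


class ScorePValueTable:
    """Exact discretized null distribution of PWM log-odds scores.

    Per-position log-odds entries are rounded onto an integer grid of
    ``bins`` steps spanning the attainable score range; the distribution of
    the integer total under the background model is an exact dynamic
    programme (convolution across positions). ``pvalue(score)`` maps a raw
    score to the tail probability of its bin's lower edge, which is
    conservative; words scored through :meth:`int_score` get the exact tail
    of their integerized score.
    """

    def __init__(self, pwm: PWM, background: np.ndarray | None = None, bins: int = 10_000):
        if bins < 2:
            raise ValueError("need at least 2 bins")
        self.pwm = pwm
        self.background = pwm.background if background is None else np.asarray(background, float)
        lod = pwm.log_odds(self.background)
        self.lod = lod
        col_min = lod.min(axis=1)
        self.min_score = float(col_min.sum())
        self.max_score = float(lod.max(axis=1).sum())
        span = self.max_score - self.min_score
        self.delta = span / bins if span > 0 else 1.0
        # integer entries, shifted per-column so the minimum is 0
        self.k = np.rint((lod - col_min[:, None]) / self.delta).astype(np.int64)
        kmax = int(self.k.max(axis=1).sum())
        pmf = np.zeros(kmax + 1)
        pmf[0] = 1.0
        for row_k in self.k:
            new = np.zeros_like(pmf)
            for letter in range(4):
                kk = row_k[letter]
                new[kk:] += pmf[: len(pmf) - kk] * self.background[letter]
            pmf = new
        self.pmf = pmf
        sf = np.cumsum(pmf[::-1])[::-1]
        self.sf = np.append(sf, 0.0)

    def int_score(self, encoded: np.ndarray) -> int:
        return int(self.k[np.arange(self.pwm.width), encoded].sum())

    def pvalue_of_int(self, kscore) -> np.ndarray | float:
        ks = np.clip(np.asarray(kscore, dtype=int), 0, len(self.sf) - 1)
        out = self.sf[ks]
        return float(out) if np.ndim(kscore) == 0 else out

    def pvalue(self, score: float) -> float:
        """Tail probability P(background word score >= score), assigned from
        the bin lower edge (never smaller than the true tail)."""
        k = int(np.floor((score - self.min_score) / self.delta))
        return self.pvalue_of_int(max(k, 0))


def score_pvalue_table(pwm: PWM, background=None, bins: int = 10_000) -> ScorePValueTable:
    return ScorePValueTable(pwm, background, bins)


# ---------------------------------------------------------------------------
# scanning


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif: str
    offset: int  # 0-based, forward coordinates of the window start
    strand: str
    score: float
    p: float


def _window_scores(enc: np.ndarray, table: ScorePValueTable):
    """Integer and raw scores for every window; windows with N masked."""
    w = table.pwm.width
    if len(enc) < w:
        return None
    wins = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (wins >= 0).all(axis=1)
    idx = np.where(wins < 0, 0, wins)
    cols = np.arange(w)
    K = table.k[cols, idx].sum(axis=1)
    raw = table.lod[cols, idx].sum(axis=1)
    return K, raw, valid


def scan_sequence(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    strands: str = "+-",
    table: ScorePValueTable | None = None,
    rc_table: ScorePValueTable | None = None,
    sequence_id: str = "",
    bins: int = 10_000,
) -> list[MotifHit]:
    """Report every window (both strands by default) whose score p-value is
    below ``p_threshold``. Reverse-strand hits are given in forward
    coordinates; windows containing N are skipped."""
    enc = _ENCODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if table is None:
        table = score_pvalue_table(pwm, bins=bins)
    hits: list[MotifHit] = []
    strand_tables = []
    if "+" in strands:
        strand_tables.append(("+", table))
    if "-" in strands:
        if rc_table is None:
            rc_table = score_pvalue_table(pwm.reverse_complement(), bins=bins)
        strand_tables.append(("-", rc_table))
    for strand, tab in strand_tables:
        res = _window_scores(enc, tab)
        if res is None:
            continue
        K, raw, valid = res
        p = tab.pvalue_of_int(K)
        take = valid & (p < p_threshold)
        for off in np.flatnonzero(take):
            hits.append(
                MotifHit(sequence_id, pwm.name, int(off), strand, float(raw[off]), float(p[off]))
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# promoters


@dataclass
class PromoterRecord:
    gene: str
    seq: str
    contig: str | None = None
    start: int | None = None  # 0-based half-open, forward genome coordinates
    end: int | None = None
    strand: str = "+"
    clipped: bool = False

    @property
    def forward_seq(self) -> str:
        """The sequence in forward genome orientation."""
        return revcomp(self.seq) if self.strand == "-" else self.seq


class PromoterSet(Mapping):
    """gene -> promoter sequence, with coordinate provenance when extracted
    from a genome."""

    def __init__(self, records: Mapping[str, PromoterRecord]):
        self._records = dict(records)

    def __getitem__(self, gene: str) -> PromoterRecord:
        return self._records[gene]

    def __iter__(self):
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def sequences(self) -> dict[str, str]:
        return {g: r.seq for g, r in self._records.items()}


def extract_promoters(
    annotation: pd.DataFrame,
    genome: Mapping[str, str],
    upstream: int = 1000,
    downstream: int = 200,
) -> PromoterSet:
    """Promoter windows around each TSS.

    ``annotation`` needs columns gene, contig, tss (0-based) and strand.
    A forward-strand gene with TSS t yields [t - upstream, t + downstream);
    a minus-strand gene yields the reverse complement of
    [t - downstream + 1, t + upstream + 1). Windows clipped at contig edges
    are flagged. A gene on a missing contig is rejected by name.
    """
    records = {}
    for row in annotation.itertuples(index=False):
        if row.contig not in genome:
            raise KeyError(f"gene {row.gene}: contig {row.contig!r} not in genome")
        contig_seq = str(genome[row.contig])
        tss = int(row.tss)
        if not 0 <= tss < len(contig_seq):
            raise ValueError(f"gene {row.gene}: TSS {tss} outside contig")
        if row.strand == "+":
            start, end = tss - upstream, tss + downstream
        elif row.strand == "-":
            start, end = tss - downstream + 1, tss + upstream + 1
        else:
            raise ValueError(f"gene {row.gene}: strand must be '+' or '-'")
        cstart, cend = max(start, 0), min(end, len(contig_seq))
        seq = contig_seq[cstart:cend]
        if row.strand == "-":
            seq = revcomp(seq)
        records[row.gene] = PromoterRecord(
            gene=row.gene, seq=seq, contig=row.contig, start=cstart, end=cend,
            strand=row.strand, clipped=(cstart != start or cend != end),
        )
    return PromoterSet(records)


def apply_variants(
    promoters: PromoterSet,
    variants: pd.DataFrame,
    population: str | None = None,
    freq_threshold: float = 0.5,
) -> tuple[PromoterSet, pd.DataFrame]:
    """Substitute a population's major alleles into each promoter.

    ``variants`` carries ref/alt/frequency columns and either genomic
    coordinates (contig + pos, 1-based, matched against each promoter's
    provenance) or promoter-local ones (gene + offset, 0-based on the
    forward-oriented promoter sequence). The alternate allele is written
    wherever its frequency exceeds ``freq_threshold``. Simple indels are
    supported; overlapping indels within one promoter are rejected. Returns
    the edited set and a substitution log.
    """
    freq_col = population if population in variants.columns else "freq"
    if freq_col not in variants.columns:
        raise ValueError(f"no frequency column {freq_col!r} in variants")
    use = variants[variants[freq_col] > freq_threshold]
    by_gene = "gene" in use.columns and "offset" in use.columns

    new_records, log_rows = {}, []
    for gene, rec in promoters.items():
        fwd = rec.forward_seq
        if by_gene:
            local = use[use["gene"] == gene].copy()
            local["local_off"] = local["offset"].astype(int)
        else:
            if rec.contig is None:
                raise ValueError(f"gene {gene}: promoter lacks genomic provenance")
            local = use[
                (use["contig"] == rec.contig)
                & (use["pos"] - 1 >= rec.start)
                & (use["pos"] - 1 < rec.end)
            ].copy()
            local["local_off"] = local["pos"].astype(int) - 1 - rec.start
        local = local.sort_values("local_off")
        prev_end = -1
        pieces, cursor = [], 0
        bad = []
        for v in local.itertuples(index=False):
            off, ref, alt = int(v.local_off), str(v.ref), str(v.alt)
            if off < prev_end:
                bad.append(off)
                continue
            if fwd[off : off + len(ref)] != ref:
                raise ValueError(
                    f"gene {gene}: reference mismatch at promoter offset {off} "
                    f"(expected {ref!r}, found {fwd[off:off + len(ref)]!r})"
                )
            pieces.append(fwd[cursor:off])
            pieces.append(alt)
            cursor = off + len(ref)
            prev_end = cursor
            log_rows.append((gene, off, ref, alt, float(getattr(v, freq_col))))
        if bad:
            raise ValueError(f"gene {gene}: overlapping indels at offsets {bad}")
        pieces.append(fwd[cursor:])
        new_fwd = "".join(pieces)
        new_seq = revcomp(new_fwd) if rec.strand == "-" else new_fwd
        new_records[gene] = replace(rec, seq=new_seq)
    log = pd.DataFrame(log_rows, columns=["gene", "offset", "ref", "alt", "freq"])
    return PromoterSet(new_records), log


def scan_promoters(
    promoters: PromoterSet | Mapping[str, str],
    pwms: Mapping[str, PWM],
    p_threshold: float = 1e-4,
    strands: str = "+-",
    bins: int = 10_000,
) -> pd.DataFrame:
    """Scan every promoter with every PWM; one row per hit."""
    seqs = promoters.sequences() if isinstance(promoters, PromoterSet) else dict(promoters)
    rows = []
    for name, pwm in pwms.items():
        table = score_pvalue_table(pwm, bins=bins)
        rc = score_pvalue_table(pwm.reverse_complement(), bins=bins) if "-" in strands else None
        for gene, seq in seqs.items():
            for h in scan_sequence(seq, pwm, p_threshold, strands, table, rc, sequence_id=gene):
                rows.append((gene, name, h.offset, h.strand, h.score, h.p))
    return pd.DataFrame(rows, columns=["gene", "motif", "offset", "strand", "score", "p"])


# ---------------------------------------------------------------------------
# enrichment and comparison


def _in_circular_window(phase, start, width, period):
    ph = np.asarray(phase, dtype=float) % period
    rel = (ph - start) % period
    return rel < width


def phase_window_enrichment(
    gene_phases: Mapping[str, float],
    target_flags: Mapping[str, bool],
    window: float = 6.0,
    step: float = 2.0,
    period: float = 24.0,
) -> pd.DataFrame:
    """Sliding circular-window Fisher exact tests for motif-target phases.

    For each window [s, s+window) tiling the clock at ``step``, builds the
    2x2 table of (has motif) x (peaks in window) over all genes with a
    phase, and reports the two-sided Fisher exact p and odds ratio. Windows
    with an empty margin get p = 1 and an empty-cell flag.
    """
    if window > period:
        raise ValueError("window cannot exceed the period")
    genes = sorted(gene_phases)
    missing = [g for g, f in target_flags.items() if f and g not in gene_phases]
    if missing:
        raise ValueError(f"flagged genes without phases: {missing[:5]}")
    phases = np.array([gene_phases[g] for g in genes], dtype=float)
    has_motif = np.array([bool(target_flags.get(g, False)) for g in genes])

    rows = []
    n_windows = int(round(period / step))
    for k in range(n_windows):
        start = k * step
        in_win = _in_circular_window(phases, start, window, period)
        a = int(np.sum(has_motif & in_win))
        b = int(np.sum(has_motif & ~in_win))
        c = int(np.sum(~has_motif & in_win))
        d = int(np.sum(~has_motif & ~in_win))
        degenerate = (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0)
        if degenerate:
            odds, p = 1.0, 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            (start, (start + window / 2) % period, a, b, c, d, float(odds), float(p), degenerate)
        )
    return pd.DataFrame(
        rows,
        columns=["window_start", "window_center", "a", "b", "c", "d",
                 "odds_ratio", "p", "empty_cell"],
    )


def motif_presence_comparison(
    hits_ref: Mapping[str, int] | Mapping[str, Iterable],
    hits_alt: Mapping[str, int] | Mapping[str, Iterable],
    gene_set: Iterable[str],
    alternative: str = "two-sided",
) -> tuple[list[str], float]:
    """Per-gene motif loss between populations plus a Fisher enrichment p.

    A gene is a loss when its reference promoter has at least one hit and
    its alternate promoter none. The Fisher test compares motif-presence
    counts between populations over ``gene_set`` (two-sided by default, so
    identical or balanced presence gives p = 1; a one-sided
    reference-greater alternative is available). Genes absent from either
    hit map are excluded with a warning.
    """

    def _count(m, g):
        v = m[g]
        return v if isinstance(v, (int, np.integer)) else len(v)

    genes, skipped = [], []
    for g in gene_set:
        if g in hits_ref and g in hits_alt:
            genes.append(g)
        else:
            skipped.append(g)
    if skipped:
        warnings.warn(
            f"motif_presence_comparison: {len(skipped)} gene(s) absent from one "
            f"promoter set were excluded", stacklevel=2,
        )
    ref_has = np.array([_count(hits_ref, g) > 0 for g in genes])
    alt_has = np.array([_count(hits_alt, g) > 0 for g in genes])
    losses = [g for g, r, a in zip(genes, ref_has, alt_has) if r and not a]
    table = [
        [int(ref_has.sum()), int((~ref_has).sum())],
        [int(alt_has.sum()), int((~alt_has).sum())],
    ]
    _, p = stats.fisher_exact(table, alternative=alternative)
    return losses, float(p)
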