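"""PWM engine: construction, exact score p-values, scanning, promoters,
variant application, phase enrichment and cross-population comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cavechrono.motifs import (
    PWM,
    apply_variants,
    builtin_motifs,
    consensus_pwm,
    extract_promoters,
    motif_presence_comparison,
    phase_window_enrichment,
    pwm_from_counts,
    revcomp,
    scan_promoters,
    scan_sequence,
    score_pvalue_table,
)


class TestPwmFromCounts:
    def test_uniform_counts_uniform_probs(self):
        pwm = pwm_from_counts(np.full((4, 4), 5.0), pseudocount=0.0)
        np.testing.assert_allclose(pwm.probs, 0.25)

    def test_deterministic_column_no_pseudocount(self):
        pwm = pwm_from_counts([[100, 0, 0, 0]], pseudocount=0.0)
        np.testing.assert_allclose(pwm.probs, [[1, 0, 0, 0]])

    def test_pseudocount_arithmetic(self):
        pwm = pwm_from_counts([[8, 2, 0, 0]], pseudocount=1.0)
        np.testing.assert_allclose(pwm.probs, np.array([[8.25, 2.25, 0.25, 0.25]]) / 11)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            pwm_from_counts([[1, 1, 1, 1], [0, 0, 0, 0]])


def _brute_force_pvalues(table):
    """Oracle: enumerate every word, weight by background, tail on the same
    integer grid the table uses."""
    w = table.pwm.width
    bg = table.background
    words = list(itertools.product(range(4), repeat=w))
    scores = np.array([table.int_score(np.array(word)) for word in words])
    probs = np.array([np.prod(bg[list(word)]) for word in words])
    return words, scores, probs


class TestScorePvalueTable:
    @pytest.mark.parametrize("background", [None, (0.4, 0.1, 0.1, 0.4)])
    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_matches_brute_force_enumeration(self, width, background):
        rng = np.random.default_rng(width)
        counts = rng.integers(0, 20, size=(width, 4)) + 0.0
        counts[counts.sum(axis=1) == 0, 0] = 1
        bg = None if background is None else np.asarray(background)
        pwm = pwm_from_counts(counts, pseudocount=1.0,
                              background=bg, name=f"w{width}")
        table = score_pvalue_table(pwm, bins=10_000)
        words, scores, probs = _brute_force_pvalues(table)
        for word, k in zip(words[:64], scores[:64]):
            oracle = probs[scores >= k].sum()
            assert table.pvalue_of_int(k) == pytest.approx(oracle, abs=1e-12)

    def test_width6_consensus_max_score_p(self):
        pwm = consensus_pwm("ACGTAC")
        table = score_pvalue_table(pwm)
        k = table.int_score(np.array([0, 1, 2, 3, 0, 1]))
        assert table.pvalue_of_int(k) == pytest.approx(0.25**6)

    def test_minimum_score_p_is_one(self):
        table = score_pvalue_table(consensus_pwm("ACGT"))
        assert table.pvalue_of_int(0) == pytest.approx(1.0)

    def test_monotone_non_increasing(self):
        table = score_pvalue_table(builtin_motifs()["RRE"], bins=2000)
        assert (np.diff(table.sf) <= 1e-15).all()


class TestScan:
    def test_default_threshold_blocks_width6_consensus(self):
        # a perfect width-6 match has p = 4^-6 ~ 2.4e-4 > 1e-4: never reported
        pwm = consensus_pwm("CACGTG")
        hits = scan_sequence("A" * 20 + "CACGTG" + "A" * 20, pwm, p_threshold=1e-4)
        assert hits == []

    def test_planted_width8_consensus_found_at_offset(self):
        pwm = builtin_motifs()["EBOX"]
        seq = "A" * 37 + pwm.consensus + "T" * 30
        hits = scan_sequence(seq, pwm, sequence_id="g")
        assert any(h.offset == 37 and h.strand == "+" for h in hits)

    def test_strand_consistency(self):
        """Scanning the reverse complement with strands swapped yields the
        same hits in forward coordinates."""
        pwm = builtin_motifs()["RRE"]
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 300)) + pwm.consensus + "ACGTAC"
        fwd = scan_sequence(seq, pwm)
        rc = scan_sequence(revcomp(seq), pwm)
        L, w = len(seq), pwm.width
        mirrored = sorted((L - w - h.offset, {"+": "-", "-": "+"}[h.strand]) for h in rc)
        assert sorted((h.offset, h.strand) for h in fwd) == mirrored

    def test_n_windows_skipped(self):
        pwm = builtin_motifs()["EBOX"]
        seq = "A" * 10 + pwm.consensus.replace("A", "N", 1) + "A" * 10
        hits = scan_sequence(seq, pwm)
        assert all(h.offset != 10 for h in hits)

    def test_short_sequence_empty(self):
        assert scan_sequence("ACG", builtin_motifs()["EBOX"]) == []


class TestExtractPromoters:
    def _genome(self):
        rng = np.random.default_rng(1)
        return {"chr1": "".join(rng.choice(list("ACGT"), 8000))}

    def test_forward_window(self):
        g = self._genome()
        ann = pd.DataFrame({"gene": ["g1"], "contig": ["chr1"], "tss": [5000], "strand": ["+"]})
        proms = extract_promoters(ann, g)
        rec = proms["g1"]
        assert (rec.start, rec.end) == (4000, 5200)
        assert rec.seq == g["chr1"][4000:5200]
        assert len(rec.seq) == 1200 and not rec.clipped

    def test_minus_strand_mirror(self):
        g = self._genome()
        ann = pd.DataFrame({"gene": ["g1"], "contig": ["chr1"], "tss": [5000], "strand": ["-"]})
        rec = extract_promoters(ann, g)["g1"]
        assert (rec.start, rec.end) == (4801, 6001)
        assert rec.seq == revcomp(g["chr1"][4801:6001])

    def test_clipping_flagged(self):
        g = self._genome()
        ann = pd.DataFrame({"gene": ["g1"], "contig": ["chr1"], "tss": [100], "strand": ["+"]})
        rec = extract_promoters(ann, g)["g1"]
        assert (rec.start, rec.end) == (0, 300) and rec.clipped

    def test_missing_contig_names_gene(self):
        ann = pd.DataFrame({"gene": ["gX"], "contig": ["chrZ"], "tss": [5], "strand": ["+"]})
        with pytest.raises(KeyError, match="gX"):
            extract_promoters(ann, self._genome())


class TestApplyVariants:
    def _promoters(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 3000))}
        ann = pd.DataFrame({"gene": ["g1"], "contig": ["chr1"], "tss": [1500], "strand": ["+"]})
        return extract_promoters(ann, genome), genome

    def test_no_variants_identity(self):
        proms, _ = self._promoters()
        out, log = apply_variants(
            proms, pd.DataFrame(columns=["contig", "pos", "ref", "alt", "freq"]))
        assert out["g1"].seq == proms["g1"].seq and len(log) == 0

    def test_single_fixed_snv(self):
        proms, genome = self._promoters()
        pos0 = 700  # genome offset within the [500, 1700) window
        ref = genome["chr1"][pos0]
        alt = "A" if ref != "A" else "C"
        variants = pd.DataFrame(
            {"contig": ["chr1"], "pos": [pos0 + 1], "ref": [ref], "alt": [alt], "freq": [1.0]}
        )
        out, log = apply_variants(proms, variants)
        diff = [i for i, (x, y) in enumerate(zip(proms["g1"].seq, out["g1"].seq)) if x != y]
        assert diff == [pos0 - 500] and len(log) == 1

    def test_variant_destroys_planted_motif(self):
        from cavechrono.motifs import PromoterRecord, PromoterSet

        pwm = builtin_motifs()["EBOX"]
        seq = "A" * 50 + pwm.consensus + "G" * 50
        proms = PromoterSet({"g1": PromoterRecord(gene="g1", seq=seq)})
        assert scan_sequence(seq, pwm)  # present before
        variants = pd.DataFrame(
            {"gene": ["g1"], "offset": [52], "ref": [pwm.consensus[2]],
             "alt": ["T"], "freq": [0.95]}
        )
        out, _ = apply_variants(proms, variants)
        assert scan_sequence(out["g1"].seq, pwm) == []

    def test_minor_allele_not_substituted(self):
        proms, genome = self._promoters()
        ref = genome["chr1"][700]
        variants = pd.DataFrame(
            {"contig": ["chr1"], "pos": [701], "ref": [ref],
             "alt": ["A" if ref != "A" else "C"], "freq": [0.3]}
        )
        out, log = apply_variants(proms, variants)
        assert out["g1"].seq == proms["g1"].seq and len(log) == 0


class TestPhaseEnrichment:
    def test_full_period_window_degenerate(self):
        phases = {f"g{i}": float(i % 24) for i in range(24)}
        flags = {g: i % 2 == 0 for i, g in enumerate(phases)}
        enr = phase_window_enrichment(phases, flags, window=24.0, step=24.0)
        assert enr["p"].iloc[0] == 1.0 and enr["odds_ratio"].iloc[0] == 1.0
        assert enr["empty_cell"].iloc[0]

    def test_complete_separation_margins_2222(self):
        # 2x2 margins all 2 with complete separation: two-sided p = 1/3
        phases = {"a": 1.0, "b": 2.0, "c": 13.0, "d": 14.0}
        flags = {"a": True, "b": True, "c": False, "d": False}
        enr = phase_window_enrichment(phases, flags, window=6.0, step=12.0, period=24.0)
        row = enr[enr["window_start"] == 0.0].iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (2, 0, 0, 2)
        assert row["p"] == pytest.approx(1 / 3)

    def test_fisher_matches_hypergeometric_summation(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 16, 4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p_sp = stats.fisher_exact([[a, b], [c, d]], "two-sided")[1]
            # direct summation over tables with fixed margins
            n, row1, col1 = a + b + c + d, a + b, a + c
            lo, hi = max(0, col1 - (c + d)), min(row1, col1)
            pmf = {x: stats.hypergeom.pmf(x, n, row1, col1) for x in range(lo, hi + 1)}
            p_hand = sum(v for v in pmf.values() if v <= pmf[a] * (1 + 1e-7))
            assert p_sp == pytest.approx(min(p_hand, 1.0), rel=1e-6)

    def test_planted_dawn_targets_recovered(self):
        rng = np.random.default_rng(5)
        phases = {f"g{i}": float(rng.uniform(0, 24)) for i in range(300)}
        flags = {g: (ph < 4) or (rng.random() < 0.05) for g, ph in phases.items()}
        enr = phase_window_enrichment(phases, flags, window=6.0, step=2.0)
        best = enr.loc[enr[~enr["empty_cell"]]["p"].idxmin()]
        from cavechrono.phase import circular_phase_distance

        assert abs(circular_phase_distance(best["window_center"], 2.0)) <= 3.0


class TestPresenceComparison:
    def test_identical_sets_no_loss(self):
        hits = {"a": 2, "b": 0, "c": 1}
        losses, p = motif_presence_comparison(hits, hits, ["a", "b", "c"])
        assert losses == [] and p == 1.0

    def test_single_disrupted_gene_listed(self):
        ref = {"a": 1, "b": 1, "c": 0}
        alt = {"a": 1, "b": 0, "c": 0}
        losses, _ = motif_presence_comparison(ref, alt, ["a", "b", "c"])
        assert losses == ["b"]

    def test_balanced_presence_p_one(self):
        ref = {"a": 1, "b": 0}
        alt = {"a": 0, "b": 1}
        with np.errstate(all="ignore"):
            losses, p = motif_presence_comparison(ref, alt, ["a", "b"])
        assert p == 1.0

    def test_missing_gene_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            losses, _ = motif_presence_comparison({"a": 1}, {"a": 1, "b": 1}, ["a", "b"])
        assert losses == []
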