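"""Rhythm-detection engine: filtering, templates, tau, exact null, JTK, BH."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cavechrono as cc
from cavechrono.design import ExpressionMatrix, SamplingDesign
from cavechrono.rhythm import (
    _bank,
    bh_adjust,
    classify_rhythmicity,
    exact_tau_null,
    filter_low_expression,
    jtk_scan,
    jtk_test,
    kendall_tau,
    reference_waveforms,
)


def _matrix(totals, design):
    n = design.n_samples
    rows = []
    for tot in totals:
        base = np.full(n, tot // n)
        base[: tot % n] += 1
        rows.append(base)
    counts = pd.DataFrame(
        rows, index=[f"g{i}" for i in range(len(totals))], columns=design.sample_names("A")
    )
    meta = pd.DataFrame(
        {
            "sample": design.sample_names("A"),
            "population": "A",
            "CT": design.sample_times,
            "replicate": np.tile(np.arange(design.replicates) + 1, design.n_timepoints),
        }
    ).set_index("sample")
    return ExpressionMatrix(counts, meta, design)


class TestFilterLowExpression:
    @pytest.mark.parametrize(
        "totals,min_total,kept",
        [
            ((99, 100), 100, 1),  # boundary: exactly 100 retained, 99 dropped
            ((50, 100, 150), 100, 2),
            ((50, 100, 150), 0, 3),  # identity at threshold 0
        ],
    )
    def test_threshold_inclusive(self, design, totals, min_total, kept):
        em = _matrix(totals, design)
        if kept < len(totals):
            with pytest.warns(UserWarning, match="removed"):
                out = filter_low_expression(em, min_total)
        else:
            out = filter_low_expression(em, min_total)
        assert len(out.genes) == kept
        assert list(out.genes) == [g for g, t in zip(em.genes, totals) if t >= min_total]


class TestReferenceWaveforms:
    def test_six_by_six_grid(self, design):
        wf = reference_waveforms(design, 24.0, 4.0)
        assert len(wf) == 6
        assert all(len(tpl) == 36 for _, tpl in wf)
        lag0 = wf[0][1]
        # maximum at the CT0 samples
        assert np.argmax(lag0) < design.replicates
        assert lag0[: design.replicates].max() == lag0.max()

    def test_periodicity(self, design):
        wf = dict(reference_waveforms(design, 24.0, 4.0))
        shifted = np.cos(2 * np.pi * (design.sample_times - 28.0) / 24.0)
        np.testing.assert_allclose(wf[4.0], np.round(shifted, 12))

    def test_lag_step_must_divide(self, design):
        with pytest.raises(ValueError, match="divide"):
            reference_waveforms(design, 24.0, 5.0)


class TestKendallTau:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 1, 2, 2], [1, 2, 1, 2], 0.0),  # C=1, D=1 over the 6 pairs
            ([5, 5, 5], [1, 2, 3], 0.0),  # degenerate all-tied x
        ],
    )
    def test_known_values(self, x, y, expected):
        assert kendall_tau(x, y) == pytest.approx(expected)

    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=12),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_scipy_taub(self, x, rnd):
        y = list(x)
        rnd.shuffle(y)
        if len(set(x)) == 1:
            return
        expected = stats.kendalltau(x, y).statistic
        assert kendall_tau(x, y) == pytest.approx(expected, abs=1e-12)


def _brute_force_s_distribution(template):
    """Independent oracle: enumerate all orderings of tie-free data."""
    n = len(template)
    y = np.asarray(template, dtype=float)
    from collections import Counter

    cnt = Counter()
    for perm in itertools.permutations(range(n)):
        x = np.asarray(perm)
        s = 0
        for i in range(n):
            for j in range(i + 1, n):
                s += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))
        cnt[s] += 1
    total = math.factorial(n)
    return {s: c / total for s, c in cnt.items()}


class TestExactTauNull:
    def test_n3_tie_free_matches_hand_enumeration(self):
        null = exact_tau_null(n=3)
        np.testing.assert_allclose(null.tau_values, [-1, -1 / 3, 1 / 3, 1])
        np.testing.assert_allclose(null.probabilities, [1 / 6, 2 / 6, 2 / 6, 1 / 6])

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_tie_free_matches_brute_force(self, n):
        null = exact_tau_null(n=n)
        oracle = _brute_force_s_distribution(np.arange(n))
        mine = dict(zip(null.s_values.tolist(), null.probabilities))
        for s, p in oracle.items():
            assert mine.get(s, 0.0) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("sizes", [(2, 2, 1), (3, 2, 2), (2, 2, 2, 2)])
    def test_tied_template_matches_brute_force(self, sizes):
        template = np.repeat(np.arange(len(sizes), dtype=float), sizes)
        null = exact_tau_null(group_sizes=sizes)
        oracle = _brute_force_s_distribution(template)
        mine = dict(zip(null.s_values.tolist(), null.probabilities))
        for s, p in oracle.items():
            assert mine.get(s, 0.0) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("sizes", [(1, 1, 1, 1), (6, 12, 12, 6), (4, 3, 2)])
    def test_normalization_and_symmetry(self, sizes):
        null = exact_tau_null(group_sizes=sizes)
        assert sum(null.probabilities) == pytest.approx(1.0)
        np.testing.assert_allclose(null.probabilities, null.probabilities[::-1])
        assert null.sf_s(-null.m_pairs) == pytest.approx(1.0)


class TestJtkTest:
    def test_noiseless_cosine_recovers_phase_and_min_p(self, design):
        series = 100 * np.cos(2 * np.pi * (design.sample_times - 8) / 24)
        res = jtk_test(series, design)
        assert res.phase == 8.0
        bank = _bank(design, 24.0, 4.0)
        assert res.p == pytest.approx(6 * bank.null.min_p)

    def test_constant_series_degenerate(self, design):
        res = jtk_test(np.full(design.n_samples, 7.0), design)
        assert res.p == 1.0 and res.amplitude == 0.0 and res.degenerate

    def test_amplitude_from_timepoint_medians(self, design):
        medians = np.array([10, 2, 2, 2, 2, 2], dtype=float)
        series = np.repeat(medians, design.replicates)
        res = jtk_test(series, design)
        assert res.amplitude == pytest.approx(4.0)  # (10 - 2) / 2

    def test_permutation_policy_agrees_with_exact_on_tie_free_data(self, design):
        rng = np.random.default_rng(3)
        x = rng.normal(size=design.n_samples)
        p_exact = jtk_test(x, design).p
        p_mc = jtk_test(x, design, tie_policy="permutation", n_draws=40_000, seed=1).p
        se = 6 * math.sqrt(max(p_exact / 6, 1e-6) * (1 - p_exact / 6) / 40_000)
        assert abs(p_mc - p_exact) < 4 * se + 1e-3

    def test_scan_matches_single_gene_path(self, design):
        rng = np.random.default_rng(7)
        X = rng.poisson(50, size=(20, design.n_samples)).astype(float)
        counts = pd.DataFrame(X, index=[f"g{i}" for i in range(20)],
                              columns=design.sample_names("A"))
        scan = jtk_scan(counts, design, population="A")
        for i in range(20):
            single = jtk_test(X[i], design)
            assert scan["p"].iloc[i] == pytest.approx(single.p)
            assert scan["phase"].iloc[i] == single.phase
            assert scan["amplitude"].iloc[i] == pytest.approx(single.amplitude)

    def test_monotone_tau_in_amplitude(self, design):
        """Median |tau| over seeds never decreases with planted amplitude."""
        from cavechrono import simulate

        med = []
        for amp in (0.25, 0.5, 1.0):
            taus = []
            for seed in range(5):
                truth = simulate.make_gene_truth(
                    n_genes=40, populations=("A",), rhythmic_fraction=1.0,
                    amplitude=amp, dispersion=0.05, seed=seed,
                )
                em, _ = simulate.simulate_expression(truth, seed=seed)
                taus.extend(jtk_scan(em.counts, em.design, population="A")["tau"])
            med.append(np.median(np.abs(taus)))
        assert med[0] <= med[1] <= med[2]


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),  # step-up collapses
            ([0.4], [0.4]),
            ([0.2, 0.2, 0.2, 0.2], [0.2, 0.2, 0.2, 0.2]),
        ],
    )
    def test_known_values(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, p):
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        # independent step-up oracle: q_(i) = min_{j >= i} p_(j) * m / j
        for rank_pos, idx in enumerate(order):
            candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
            assert q[idx] == pytest.approx(min(1.0, min(candidates)), abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestClassify:
    def test_label_rules(self):
        df = pd.DataFrame({"p": [0.001, 0.6, 0.2], "q": [0.04, 0.9, 0.3]})
        labels = classify_rhythmicity(df, 0.05, 0.5)
        assert list(labels) == ["rhythmic", "arrhythmic", "indeterminate"]
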