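"""Differential rhythmicity between population pairs.

The score for each gene is S_DR = (Z_P + Z_R)/2, where Z_P standardizes the
change in periodicity, log(p1) - log(p2) of the cycling-test p-values, and
Z_R standardizes the change in oscillation robustness, log2(A2/A1) of the
amplitudes. Both are z-scored against the empirical mean/SD over the genes
included for that pair (cycling p < 1 in either population, the default
inclusion rule), so a positive S_DR means population 2 is the more rhythmic
of the pair. Significance comes from a Gaussian fitted to the empirical
S_DR distribution, with BH correction.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .rhythm import bh_adjust

__all__ = [
    "sdr_scores",
    "sdr_pvalues",
    "loss_sets",
    "set_overlap_test",
    "pvalue_shift_test",
]


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    if sd == 0:
        warnings.warn("degenerate spread: all deltas identical; z-scores set to 0",
                      stacklevel=3)
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def sdr_scores(
    results_pop1: pd.DataFrame,
    results_pop2: pd.DataFrame,
    inclusion_p: float = 1.0,
    amplitude_floor: float | None = None,
) -> pd.DataFrame:
    """Per-gene S_DR between two rhythm tables sharing a gene universe.

    Genes enter when their cycling p is below ``inclusion_p`` in either
    population. Zero amplitudes are floored at half the smallest positive
    amplitude observed across both tables (or ``amplitude_floor``), keeping
    the log-ratio finite; the floor used is recorded in ``attrs``.
    Swapping the populations negates Z_P, Z_R and S_DR exactly.
    """
    t1 = results_pop1.set_index("gene") if "gene" in results_pop1 else results_pop1
    t2 = results_pop2.set_index("gene") if "gene" in results_pop2 else results_pop2
    common = t1.index.intersection(t2.index)
    if len(common) == 0:
        raise ValueError("the two rhythm tables share no genes")
    t1, t2 = t1.loc[common], t2.loc[common]

    include = (t1["p"] < inclusion_p) | (t2["p"] < inclusion_p)
    t1, t2 = t1[include], t2[include]
    if len(t1) == 0:
        raise ValueError("no genes pass the inclusion rule")

    amps = np.concatenate([t1["amplitude"].to_numpy(), t2["amplitude"].to_numpy()])
    if amplitude_floor is None:
        positive = amps[amps > 0]
        amplitude_floor = float(positive.min() / 2) if len(positive) else 1.0
    a1 = np.maximum(t1["amplitude"].to_numpy(), amplitude_floor)
    a2 = np.maximum(t2["amplitude"].to_numpy(), amplitude_floor)
    # p-values clipped away from 0 only to keep the log finite
    p1 = np.clip(t1["p"].to_numpy(), 1e-300, None)
    p2 = np.clip(t2["p"].to_numpy(), 1e-300, None)

    delta_period = np.log(p1) - np.log(p2)
    # written as a difference of logs so swapping populations negates exactly
    delta_amp = np.log2(a2) - np.log2(a1)
    zp = _zscore(delta_period)
    zr = _zscore(delta_amp)

    pop1 = t1["population"].iloc[0] if "population" in t1 else "pop1"
    pop2 = t2["population"].iloc[0] if "population" in t2 else "pop2"
    out = pd.DataFrame(
        {
            "gene": t1.index,
            "population1": pop1,
            "population2": pop2,
            "Z_P": zp,
            "Z_R": zr,
            "S_DR": (zp + zr) / 2,
        }
    ).reset_index(drop=True)
    out.attrs["amplitude_floor"] = amplitude_floor
    return out


def sdr_pvalues(table: pd.DataFrame, tail: str = "upper") -> pd.DataFrame:
    """Gaussian p-values from the fit to the empirical S_DR distribution.

    ``tail`` is ``upper`` (population 2 more rhythmic), ``lower`` or
    ``two-sided``. Requires at least 10 genes for a stable fit. Degenerate
    (zero-SD) score distributions give uniform p = 1 with a warning.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 genes to fit the empirical Gaussian")
    s = table["S_DR"].to_numpy()
    mu, sd = float(s.mean()), float(s.std(ddof=1))
    out = table.copy()
    if sd == 0:
        warnings.warn("degenerate S_DR distribution (zero SD); p set to 1", stacklevel=2)
        out["p"] = 1.0
        out["q"] = 1.0
        return out
    z = (s - mu) / sd
    if tail == "upper":
        p = stats.norm.sf(z)
    elif tail == "lower":
        p = stats.norm.cdf(z)
    elif tail == "two-sided":
        p = 2 * stats.norm.sf(np.abs(z))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    out["p"] = np.minimum(p, 1.0)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def loss_sets(
    labels: Mapping[str, pd.Series],
    reference: str,
) -> dict[str, set[str]]:
    """Named gene sets describing rhythmicity loss relative to a reference.

    ``labels`` maps population name to a gene-indexed Series of
    rhythmic/arrhythmic/indeterminate labels. Emits: rhythmic_in_reference,
    lost_in_all (rhythmic in reference, arrhythmic in every comparison
    population), lost_in_at_least_one, and rhythmic_in_all.
    """
    if reference not in labels:
        raise KeyError(f"unknown reference population {reference!r}")
    comparisons = [p for p in labels if p != reference]
    if not comparisons:
        raise ValueError("need at least one comparison population")
    ref = labels[reference]
    rhythmic_ref = set(ref.index[ref == "rhythmic"])

    arr = {p: set(labels[p].index[labels[p] == "arrhythmic"]) for p in comparisons}
    rhy = {p: set(labels[p].index[labels[p] == "rhythmic"]) for p in comparisons}

    lost_all = {g for g in rhythmic_ref if all(g in arr[p] for p in comparisons)}
    lost_any = {g for g in rhythmic_ref if any(g in arr[p] for p in comparisons)}
    rhythmic_all = {g for g in rhythmic_ref if all(g in rhy[p] for p in comparisons)}
    return {
        "rhythmic_in_reference": rhythmic_ref,
        "lost_in_all": lost_all,
        "lost_in_at_least_one": lost_any,
        "rhythmic_in_all": rhythmic_all,
    }


def set_overlap_test(set_a: Iterable, set_b: Iterable, universe_size: int) -> tuple[int, float]:
    """Upper-tail hypergeometric probability of an overlap at least as large
    as observed between two gene sets drawn from a common universe."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(a & b)
    if k > min(len(a), len(b)):
        raise ValueError("overlap exceeds the smaller set")  # unreachable with real sets
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, min(p, 1.0)


def pvalue_shift_test(
    gene_set: Iterable[str],
    results_ref: pd.DataFrame,
    results_other: pd.DataFrame,
) -> tuple[str, float]:
    """Paired Wilcoxon signed-rank comparison of cycling p-values over a
    gene set (e.g., annotated circadian genes) between two populations.

    Returns ``(direction, p)`` where direction names the population with
    stochastically smaller cycling p-values (i.e., the more rhythmic one),
    or "none" when all paired differences are zero.
    """
    genes = list(gene_set)
    if len(genes) < 6:
        raise ValueError("need at least 6 genes for the signed-rank test")
    r = results_ref.set_index("gene") if "gene" in results_ref else results_ref
    o = results_other.set_index("gene") if "gene" in results_other else results_other
    missing = [g for g in genes if g not in r.index or g not in o.index]
    if missing:
        raise KeyError(f"genes absent from a rhythm table: {missing[:5]}")
    d = r.loc[genes, "p"].to_numpy() - o.loc[genes, "p"].to_numpy()
    if np.all(d == 0):
        return "none", 1.0
    stat_p = stats.wilcoxon(d, zero_method="wilcox").pvalue
    direction = "reference more rhythmic" if np.median(d[d != 0]) < 0 else "other more rhythmic"
    return direction, float(stat_p)
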