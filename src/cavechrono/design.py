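"""Core containers shared across the pipeline.

The study design is a single 24-h circadian cycle sampled under constant
darkness: six timepoints at 4-h spacing (CT0, CT4, ..., CT20) with six
biological replicates per timepoint and population. :class:`SamplingDesign`
carries that layout; :class:`ExpressionMatrix` couples a gene x sample count
matrix with the per-sample metadata (population, circadian time, replicate)
every downstream stage needs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SamplingDesign", "ExpressionMatrix", "substream", "DEFAULT_DESIGN"]


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Derive a named, independent random substream from one top-level seed.

    Stage names are hashed into a ``SeedSequence`` spawn key so that every
    stage of a run draws from its own stream, all reproducible from the
    single ``seed``.
    """
    key = []
    for name in names:
        if isinstance(name, int):
            key.append(name & 0x7FFFFFFF)
        else:
            digest = hashlib.sha256(str(name).encode()).digest()
            key.append(int.from_bytes(digest[:4], "big"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SamplingDesign:
    """Layout of one circadian time-course.

    Parameters
    ----------
    timepoints :
        Circadian times (CT, hours) at which samples were taken; strictly
        increasing, all within ``[0, period)``.
    replicates :
        Biological replicates per timepoint.
    period :
        Length of the cycle in hours (24 for a circadian design).
    """

    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    replicates: int = 6
    period: float = 24.0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tp)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")
        if len(tp) < 2:
            raise ValueError("need at least two timepoints")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if tp[0] < 0 or tp[-1] >= self.period:
            raise ValueError("timepoints must lie within [0, period)")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def n_samples(self) -> int:
        return self.n_timepoints * self.replicates

    @property
    def sample_times(self) -> np.ndarray:
        """CT of every sample, timepoint-major (replicates contiguous)."""
        return np.repeat(np.asarray(self.timepoints, dtype=float), self.replicates)

    def sample_names(self, population: str) -> list[str]:
        return [
            f"{population}_CT{int(t):02d}_r{r + 1}"
            for t in self.timepoints
            for r in range(self.replicates)
        ]


DEFAULT_DESIGN = SamplingDesign()


@dataclass
class ExpressionMatrix:
    """Gene x sample integer count matrix with sample metadata.

    ``counts`` is indexed by gene with one column per sample; ``meta`` is
    indexed by sample with columns ``population``, ``CT`` and ``replicate``.
    Every sample maps to exactly one (population, CT, replicate) triple.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    design: SamplingDesign = field(default_factory=SamplingDesign)

    def __post_init__(self) -> None:
        required = {"population", "CT", "replicate"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("counts columns and metadata rows must match 1:1, in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        triples = self.meta[["population", "CT", "replicate"]]
        if triples.duplicated().any():
            dup = triples[triples.duplicated()].index[0]
            raise ValueError(f"duplicate (population, CT, replicate) triple at sample {dup!r}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.meta["population"]))

    def subset_population(self, population: str) -> "ExpressionMatrix":
        """Columns of one population, ordered by CT then replicate."""
        mask = self.meta["population"] == population
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        meta = self.meta.loc[mask].sort_values(["CT", "replicate"])
        return ExpressionMatrix(self.counts[meta.index], meta, self.design)

    def gene_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)
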