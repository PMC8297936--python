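import numpy as np
import pandas as pd
import pytest

from cavechrono.design import SamplingDesign
from cavechrono import simulate


@pytest.fixture(scope="session")
def design():
    return SamplingDesign()


@pytest.fixture(scope="session")
def null_scan():
    """JTK results for 2,000 truly flat genes (shared across calibration tests)."""
    import cavechrono as cc

    truth = simulate.make_gene_truth(
        n_genes=2000, populations=("A",), rhythmic_fraction=0.0, seed=101
    )
    em, _ = simulate.simulate_expression(truth, seed=101)
    return cc.jtk_scan(em.counts, em.design, population="A")


@pytest.fixture()
def toy_rhythm_tables():
    """Two small hand-set rhythm tables sharing a 5-gene universe."""

    def table(pop, ps, amps):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(ps))],
                "population": pop,
                "tau": 0.0,
                "p": ps,
                "phase": 0.0,
                "amplitude": amps,
            }
        )

    t1 = table("P1", [0.001, 0.5, 0.9, 0.05, 0.2], [4.0, 1.0, 0.5, 2.0, 1.5])
    t2 = table("P2", [0.8, 0.01, 0.9, 0.6, 0.2], [0.5, 3.0, 0.5, 0.4, 1.5])
    return t1, t2
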