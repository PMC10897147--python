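import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers

from turnoverms import simulate as sim
from turnoverms.matrix import FaMatrix, make_sample_table


@pytest.fixture(scope="session")
def small_design():
    return sim.CohortDesign(sexes=("M",), replicates=3, seed=11)


@pytest.fixture(scope="session")
def small_panel():
    return sim.make_panel(n_proteins=60, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_design, small_panel):
    return sim.simulate_truth(small_design, small_panel)


@pytest.fixture(scope="session")
def default_truth():
    """The default 500-protein, two-sex cohort at its stated conditions."""
    design = sim.CohortDesign(seed=1)
    panel = sim.make_panel(seed=1)
    return sim.simulate_truth(design, panel)


@pytest.fixture
def toy_fa():
    """4 proteins x 6 samples (3 ages x 2 replicates), hand-set values."""
    ages = [12, 12, 15, 15, 18, 18]
    records = [
        {
            "sample": f"s{i}",
            "age": a,
            "sex": "M",
            "fraction": "bulk",
            "treatment": "none",
            "replicate": i % 2 + 1,
        }
        for i, a in enumerate(ages)
    ]
    values = pd.DataFrame(
        np.array(
            [
                [0.10, 0.12, 0.30, 0.32, 0.20, 0.22],
                [0.50, 0.52, 0.40, 0.42, 0.30, 0.32],
                [0.05, 0.06, 0.05, 0.07, 0.06, 0.05],
                [0.80, 0.82, 0.70, 0.72, 0.60, 0.62],
            ]
        ),
        index=["P1", "P2", "P3", "P4"],
        columns=[r["sample"] for r in records],
    )
    return FaMatrix(values, make_sample_table(records))
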