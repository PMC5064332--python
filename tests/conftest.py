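import numpy as np
import pandas as pd
import pytest

from twinlia import SimulationConfig, VarianceComponents, simulate_pairs


@pytest.fixture(scope="session")
def ade_truth():
    """The fitted with-severe variance composition used throughout."""
    return VarianceComponents(a2=0.27, d2=0.25, e2=0.48)


@pytest.fixture(scope="session")
def large_cohort(ade_truth):
    """One large simulated cohort shared by the slower statistical tests."""
    cfg = SimulationConfig(
        components=ade_truth, n_mz=20000, n_dz=20000, seed=20260922
    )
    return simulate_pairs(cfg)


@pytest.fixture()
def small_records():
    return pd.DataFrame(
        {
            "pair_id": [1, 2, 3, 4],
            "zygosity": ["MZ", "MZ", "DZ", "DZ"],
            "score1": [0, 3, 1, 0],
            "score2": [0, 2, 1, 2],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
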