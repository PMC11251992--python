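import numpy as np
import pandas as pd
import pytest

from neoscreen import SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A one-allele, single-plate synthetic screen shared across tests."""
    config = SimulationConfig(seed=11, n_variants=9, n_alleles=1)
    return config, simulate_screen(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_screen_records():
    """Hand-built screen records: peptides a-d on one allele, one QC-passing plate."""
    records = pd.DataFrame(
        {
            "peptide": ["a", "b", "c", "d"],
            "allele": ["A*02:01"] * 4,
            "well": ["C3", "D3", "E3", "F3"],
            "plate_id": ["P1"] * 4,
            "rfu_ratio": [1.0, 2.0, 3.0, 4.0],
            "percent_deltaf": [0.0, 10.0, 20.0, 30.0],
            "rz_score": [1.0, 6.0, 7.0, 2.0],
            "stable_binder": [False, True, True, False],
        }
    )
    return records
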