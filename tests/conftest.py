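import numpy as np
import pandas as pd
import pytest

from lunarice import GeneModel, SimConfig, simulate_all
from lunarice.diffexpr import ExpressionMatrix


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down study: 40 genes on 300 kb, 24 miRNAs, 12 samples."""
    return SimConfig(seed=11, n_genes=40, genome_length=300_000, n_mirnas=24)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_all(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_matrix(values: dict, meta_rows: list[dict]) -> ExpressionMatrix:
    """Tiny expression matrix from a dict of molecule -> list of values."""
    meta = pd.DataFrame(meta_rows)
    df = pd.DataFrame(values, index=meta["sample_id"]).T
    return ExpressionMatrix(df, meta)


@pytest.fixture()
def six_sample_meta() -> list[dict]:
    return [
        {"sample_id": "TC1", "group": "control", "stage": "tillering", "individual": 1},
        {"sample_id": "TC2", "group": "control", "stage": "tillering", "individual": 2},
        {"sample_id": "TC3", "group": "control", "stage": "tillering", "individual": 3},
        {"sample_id": "TS1", "group": "flight", "stage": "tillering", "individual": 1},
        {"sample_id": "TS2", "group": "flight", "stage": "tillering", "individual": 2},
        {"sample_id": "TS3", "group": "flight", "stage": "tillering", "individual": 3},
    ]
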