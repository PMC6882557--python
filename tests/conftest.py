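import numpy as np
import pandas as pd
import pytest

import driftomics as d


@pytest.fixture(scope="session")
def small_config():
    return d.SynthConfig(n_genes=400, n_metabolites=30, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return d.generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    return d.generate_dataset(d.SynthConfig(seed=0))


@pytest.fixture
def toy_metadata():
    groups = ["young"] * 3 + ["old"] * 3
    return pd.DataFrame(
        {"sample": [f"s{i}" for i in range(6)], "group": groups}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
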