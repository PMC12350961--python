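import numpy as np
import pandas as pd
import pytest

from fidlong.orgel_model import OrgelParams
from fidlong import synthetic_data as sd


@pytest.fixture(scope="session")
def params() -> OrgelParams:
    return OrgelParams()


@pytest.fixture(scope="session")
def tiny_config() -> sd.SynthConfig:
    """A panel small enough for second-scale end-to-end runs."""
    return sd.SynthConfig(n_strains=8, n_chromosomes=2, markers_per_chromosome=5)


@pytest.fixture(scope="session")
def noise_free_dataset(tiny_config):
    cfg = sd.SynthConfig(
        n_strains=8,
        n_chromosomes=2,
        markers_per_chromosome=5,
        trait_cv=0.0,
        od_noise_sd=0.0,
    )
    return sd.generate_all(cfg, seed=42)


@pytest.fixture(scope="session")
def default_dataset():
    """Default-noise synthetic dataset on a mid-sized panel."""
    cfg = sd.SynthConfig(n_strains=40)
    return sd.generate_all(cfg, seed=7)
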